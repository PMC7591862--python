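"""Synthetic BOLD cohorts: control signals, lesioned patients, longitudinal
schedules.

Signal model
------------
Voxel ``v`` of network ``n(v)`` with functional hemisphere ``h(v)`` (the
anatomical hemisphere in the cerebrum, the contralateral one in the
cerebellum) has the series

    x_v(t) = lambda * s_{n(v)}(t) + eta * g_{n(v), h(v)}(t) + sigma * e_v(t)

with independent zero-mean unit-variance white signals, so the expected
Pearson correlation between two voxels of the same network and functional
hemisphere is (lambda^2 + eta^2) / (lambda^2 + eta^2 + sigma^2), and
lambda^2 / (...) across hemispheres.

Lesion model
------------
A lesion scales voxel ``v``'s structured loadings by ``f_v = 1 - gamma *
p_v`` and moves the removed variance into noise, so per-voxel variance is
preserved.  ``p_v`` is the generative proximity:

* functional mode — the fraction of structured variance voxel ``v`` shares
  with any tumour voxel: network co-membership weighted lambda^2, plus
  eta^2 when the functional hemisphere also matches.  With eta = 0 this
  reduces to plain network co-membership.  Because the cerebellar
  representation is crossed, a left-cerebral tumour propagates more
  strongly into the *right* cerebellum.
* spatial mode — exp(-d_v / tau) with ``d_v`` the mm distance to the
  nearest tumour voxel.

At gamma = 0 the patient series is bit-identical to the control draw for
the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VoxelMask
from .images import (
    SegmentationVolume,
    TimeSeriesImage,
)
from .phantom import Phantom

__all__ = [
    "SignalModel",
    "LesionSpec",
    "SessionSpec",
    "LongitudinalSchedule",
    "simulate_control",
    "simulate_patient",
    "simulate_longitudinal",
    "functional_proximity",
    "spatial_proximity",
    "segmentation_from_mask",
]


@dataclass(frozen=True)
class SignalModel:
    """Loadings of the generative BOLD model (all unitless)."""

    n_timepoints: int = 300
    network_loading: float = 0.55  # lambda
    hemisphere_loading: float = 0.35  # eta
    noise_sd: float = 1.0  # sigma

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need T >= 2")
        if min(self.network_loading, self.hemisphere_loading, self.noise_sd) < 0:
            raise ValueError("loadings must be >= 0")
        if self.structured_variance + self.noise_sd**2 <= 0:
            raise ValueError("model is identically zero")

    @property
    def structured_variance(self) -> float:
        return self.network_loading**2 + self.hemisphere_loading**2

    @property
    def total_variance(self) -> float:
        return self.structured_variance + self.noise_sd**2

    def expected_r(self, same_network: bool, same_functional_hemisphere: bool) -> float:
        if not same_network:
            return 0.0
        shared = self.network_loading**2
        if same_functional_hemisphere:
            shared += self.hemisphere_loading**2
        return shared / self.total_variance


@dataclass(frozen=True)
class LesionSpec:
    """A connectivity perturbation tied to a tumour mask."""

    tumour_mask: VoxelMask
    mode: str = "functional"  # or "spatial"
    gamma: float = 0.8
    tau_mm: float = 6.0  # spatial decay length, spatial mode only

    def __post_init__(self) -> None:
        if self.mode not in ("functional", "spatial"):
            raise ValueError(f"unknown lesion mode {self.mode!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.mode == "spatial" and self.tau_mm <= 0:
            raise ValueError("tau_mm must be > 0 in spatial mode")
        if self.gamma > 0 and self.tumour_mask.empty():
            raise ValueError("tumour mask is empty")


def functional_proximity(phantom: Phantom, tumour: VoxelMask, model: SignalModel) -> np.ndarray:
    """Generative functional proximity p_v in [0, 1] per masked voxel."""
    in_tumour = np.isin(phantom.mask.indices, tumour.indices)
    if not in_tumour.any():
        return np.zeros(phantom.n_voxels)
    t_nets = set(phantom.network[in_tumour].tolist())
    t_pairs = set(
        zip(
            phantom.network[in_tumour].tolist(),
            phantom.functional_hemisphere[in_tumour].tolist(),
        )
    )
    lam2 = model.network_loading**2
    eta2 = model.hemisphere_loading**2
    shared = np.zeros(phantom.n_voxels)
    same_net = np.isin(phantom.network, list(t_nets))
    shared[same_net] += lam2
    pair_match = np.array(
        [
            (n, h) in t_pairs
            for n, h in zip(phantom.network, phantom.functional_hemisphere)
        ]
    )
    shared[pair_match] += eta2
    denom = lam2 + eta2
    return shared / denom if denom > 0 else np.zeros(phantom.n_voxels)


def spatial_proximity(phantom: Phantom, tumour: VoxelMask, tau_mm: float) -> np.ndarray:
    """exp(-d/tau) with d the mm distance to the nearest tumour voxel."""
    dist_vol = ndimage.distance_transform_edt(
        ~tumour.volume, sampling=phantom.grid.spacing
    )
    d = dist_vol.ravel()[phantom.mask.indices]
    return np.exp(-d / tau_mm)


def _lesion_factor(phantom: Phantom, model: SignalModel, lesions) -> np.ndarray:
    """Combined per-voxel loading factor f_v = prod(1 - gamma_i p_i,v)."""
    f = np.ones(phantom.n_voxels)
    for lesion in lesions:
        if lesion is None or lesion.gamma == 0:
            continue
        if lesion.mode == "functional":
            p = functional_proximity(phantom, lesion.tumour_mask, model)
        else:
            p = spatial_proximity(phantom, lesion.tumour_mask, lesion.tau_mm)
        f *= 1.0 - lesion.gamma * p
    return f


def _draw_series(
    phantom: Phantom, model: SignalModel, factor: np.ndarray, seed: int
) -> np.ndarray:
    """Shared draw path: identical signals for identical seeds, any factor."""
    rng = np.random.default_rng(seed)
    t = model.n_timepoints
    s = rng.standard_normal((7, t))
    g = rng.standard_normal((7, 2, t))
    eps = rng.standard_normal((phantom.n_voxels, t))
    structured = (
        model.network_loading * s[phantom.network]
        + model.hemisphere_loading * g[phantom.network, phantom.functional_hemisphere]
    )
    # variance removed from the structured part is returned as noise
    noise_sd = np.sqrt(
        model.noise_sd**2 + (1.0 - factor**2) * model.structured_variance
    )
    return factor[:, None] * structured + noise_sd[:, None] * eps


def simulate_control(
    phantom: Phantom, model: SignalModel, seed: int, subject_id: str = ""
) -> TimeSeriesImage:
    """One healthy control scan."""
    data = _draw_series(phantom, model, np.ones(phantom.n_voxels), seed)
    return TimeSeriesImage(
        phantom.grid, phantom.mask, data, subject_id=subject_id,
        session_label="control",
    )


def segmentation_from_mask(
    grid, tumour: VoxelMask, code: int = 2
) -> SegmentationVolume:
    """Label every tumour voxel with one tissue code (default enhancing)."""
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[tumour.volume] = code
    return SegmentationVolume(grid, labels)


def simulate_patient(
    phantom: Phantom,
    model: SignalModel,
    lesion: LesionSpec,
    seed: int,
    subject_id: str = "",
    extra_lesions: tuple = (),
    segmentation: SegmentationVolume | None = None,
    session_label: str = "pre",
    session_index: int = 0,
) -> tuple[TimeSeriesImage, SegmentationVolume]:
    """One lesioned patient scan plus its tumour segmentation.

    With gamma = 0 the series equals :func:`simulate_control` at the same
    seed.  Total per-voxel variance is preserved for any gamma.
    """
    factor = _lesion_factor(phantom, model, (lesion, *extra_lesions))
    data = _draw_series(phantom, model, factor, seed)
    ts = TimeSeriesImage(
        phantom.grid, phantom.mask, data, subject_id=subject_id,
        session_label=session_label, session_index=session_index,
    )
    if segmentation is None:
        segmentation = segmentation_from_mask(phantom.grid, lesion.tumour_mask)
    return ts, segmentation


@dataclass(frozen=True)
class SessionSpec:
    """One scheduled scan: lesion state and what the radiologist would see."""

    label: str  # pre | post | followup-k
    segmentation: SegmentationVolume
    lesion: LesionSpec | None = None
    recurrence_site: VoxelMask | None = None
    recurrence_gamma: float = 0.0
    recurrence_silent: bool = True  # perturbed but not yet segmented
    recurrence_tau_mm: float = 3.0


@dataclass(frozen=True)
class LongitudinalSchedule:
    sessions: tuple[SessionSpec, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sessions]
        if labels and labels[0] != "pre":
            raise ValueError("schedule must start with the pre-surgical session")
        if len(labels) > 1 and labels[1] != "post":
            raise ValueError("second session must be post-surgical")
        for i, s in enumerate(self.sessions):
            if i >= 2 and not s.label.startswith("followup"):
                raise ValueError("sessions after post must be follow-ups")
            if (
                s.recurrence_site is not None
                and s.recurrence_silent
                and s.recurrence_gamma > 0
            ):
                seen = False
                for later in self.sessions[i + 1:]:
                    en = later.segmentation.enhancing_necrotic_mask()
                    if s.recurrence_site.intersect(en).n_voxels == s.recurrence_site.n_voxels:
                        seen = True
                        break
                if not seen:
                    raise ValueError(
                        f"silent recurrence at session {i} never appears as "
                        "enhancing/necrotic segmentation later"
                    )


def simulate_longitudinal(
    phantom: Phantom,
    model: SignalModel,
    schedule: LongitudinalSchedule,
    seed: int,
    subject_id: str = "",
) -> list[tuple[TimeSeriesImage, SegmentationVolume]]:
    """One scan per scheduled session; segmentations returned as scheduled."""
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(schedule.sessions)) % (2**31)
    for i, (sess, s_seed) in enumerate(zip(schedule.sessions, child_seeds)):
        lesions = [sess.lesion]
        if sess.recurrence_site is not None and sess.recurrence_gamma > 0:
            lesions.append(
                LesionSpec(
                    sess.recurrence_site,
                    mode="spatial",
                    gamma=sess.recurrence_gamma,
                    tau_mm=sess.recurrence_tau_mm,
                )
            )
        factor = _lesion_factor(phantom, model, lesions)
        data = _draw_series(phantom, model, factor, int(s_seed))
        ts = TimeSeriesImage(
            phantom.grid, phantom.mask, data, subject_id=subject_id,
            session_label=sess.label, session_index=i,
        )
        out.append((ts, sess.segmentation))
    return out
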