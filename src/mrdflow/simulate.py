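"""Synthetic labeled flow cytometry cohorts for the CLL MRD workflow.

Generates 13-channel event data with the statistical structure the workflow
assumes: 14 immunophenotypically distinct populations, rare clonal B-cell
(CLL) fractions down to 0.001% of white cells, uncompensated spectral
overlap, cell aggregates (FSC-A >> FSC-H doublets) and debris.

Intensity model
---------------
Each class has a per-channel lognormal intensity template: the log10
intensity of channel c for an event of class k is N(mu_kc, sigma_kc),
exponentiated and clipped to the instrument range [0, 262143] (an 18-bit
digitizer). Surface-immunoglobulin light-chain structure is encoded as
mixture modes: clonal CLL cells are dim-restricted to one light chain,
polytypic B cells draw kappa- or lambda-positive modes 60:40. Fluorescence
channels are then mixed through a fixed diagonal-dominant spillover matrix —
the emitted data are uncompensated, as the classifier expects.

Determinism: every case is generated from its own integer seed; cohorts
derive per-case seeds from a master seed by a fixed counter scheme
(``seed_i = (master * 1_000_003 + i) mod 2^31``), so any single case is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs_io import CaseSample, EventMatrix
from .ontology import (
    CHANNEL_NAMES,
    CLASSES,
    N_CHANNELS,
    PANEL,
    WBC_EXCLUDED_CLASSES,
)

__all__ = [
    "MarkerProfile",
    "SpilloverMatrix",
    "CaseConfig",
    "DilutionPlan",
    "default_profiles",
    "default_spillover",
    "default_class_mix",
    "simulate_case",
    "spike_dilution",
    "make_cohort",
    "cohort_manifest",
    "case_seed",
]

INSTRUMENT_MAX = 262_143.0  # 18-bit digitizer full scale

_FLUORO_SLICE = slice(3, 13)  # fluorescence columns within the panel order


@dataclass(frozen=True)
class MarkerProfile:
    """Lognormal intensity template for one cell class.

    ``loc``/``scale`` are log10-intensity mean and SD per channel, in panel
    order. ``modes`` optionally defines a mixture over channel-location
    overrides (e.g. the kappa/lambda split of polytypic B cells): a list of
    ``(weight, {channel_name: loc})`` entries; weights must sum to 1.
    """

    class_name: str
    loc: np.ndarray
    scale: np.ndarray
    modes: tuple[tuple[float, Mapping[str, float]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "loc", np.asarray(self.loc, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        if self.loc.shape != (N_CHANNELS,) or self.scale.shape != (N_CHANNELS,):
            raise ValueError("profile must define all 13 channels")
        if not (self.scale > 0).all():
            raise ValueError("spreads must be positive")
        if self.modes:
            w = sum(m[0] for m in self.modes)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("mode weights must sum to 1")


@dataclass(frozen=True)
class SpilloverMatrix:
    """10x10 mixing matrix over fluorescence channels (uncompensated optics).

    Row i gives the fractional detection of fluorochrome i across the 10
    detectors; diagonal-dominant (diagonal >= 0.7), all entries >= 0.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (10, 10):
            raise ValueError("spillover matrix must be 10x10")
        if (v < 0).any():
            raise ValueError("spillover entries must be non-negative")
        if (np.diag(v) < 0.7).any():
            raise ValueError("spillover diagonal entries must be >= 0.7")

    def mix(self, fluorescence: np.ndarray) -> np.ndarray:
        """Apply spectral mixing: observed_j = sum_i true_i * S[i, j]."""
        return fluorescence @ self.values

    @property
    def invertible(self) -> bool:
        return np.linalg.matrix_rank(self.values) == 10


def default_spillover() -> SpilloverMatrix:
    """Fixed diagonal-dominant spillover with nearest-detector crosstalk."""
    s = np.eye(10) * 0.92
    for i in range(10):
        if i > 0:
            s[i, i - 1] = 0.03
        if i < 9:
            s[i, i + 1] = 0.03
        if i > 1:
            s[i, i - 2] = 0.01
        if i < 8:
            s[i, i + 2] = 0.01
    return SpilloverMatrix(s)


# --------------------------------------------------------------------------
# Class templates
#
# log10 intensity conventions (18-bit scale): negative ~1.2, dim ~2.3,
# positive ~3.2, bright ~3.9-4.3. Scatter locations are log10 of typical
# area/height pulse values; aggregates are the one class whose FSC-A
# location sits far above its FSC-H location.

_NEG = 1.2
_DIM = 2.3
_POS = 3.2
_BRIGHT = 3.9


def _prof(
    name: str,
    fsc_a: float,
    fsc_h: float,
    ssc_a: float,
    fluoro: Sequence[float],
    scatter_sd: float = 0.10,
    fluoro_sd: float = 0.18,
    modes: tuple[tuple[float, Mapping[str, float]], ...] = (),
    sd_override: Mapping[str, float] | None = None,
) -> MarkerProfile:
    loc = np.array([fsc_a, fsc_h, ssc_a, *fluoro], dtype=float)
    scale = np.array([scatter_sd] * 3 + [fluoro_sd] * 10, dtype=float)
    if sd_override:
        for ch, sd in sd_override.items():
            scale[CHANNEL_NAMES.index(ch)] = sd
    return MarkerProfile(name, loc, scale, modes)


def default_profiles(atypical_cd20_bright: bool = False) -> dict[str, MarkerProfile]:
    """Marker templates for all 14 classes, pairwise separable by design.

    Fluorescence order: CD5, CD19, CD20, CD22, CD38, CD43, CD45, CD200,
    Kappa, Lambda.

    The CLL template is the canonical phenotype — CD5+ CD19+ CD20-dim
    CD22-dim CD43+ CD200-bright with dim kappa restriction. With
    ``atypical_cd20_bright`` the clone takes the atypical-CLL variant
    phenotype: CD20 raised to the bright level of normal B cells, brighter
    surface light chain, and moderately dimmer (still positive) CD200 — a
    shift toward mature-B appearance that a network never exposed to it
    tends to misread.
    """
    if atypical_cd20_bright:
        cll_cd20, cll_cd200, cll_kappa = _BRIGHT, 3.4, 3.1
    else:
        cll_cd20, cll_cd200, cll_kappa = _DIM, _BRIGHT, _DIM
    p = {
        "CLL_cells": _prof(
            "CLL_cells", 4.68, 4.66, 4.00,
            [_POS, _POS, cll_cd20, _DIM, 1.8, 3.0, 3.6, cll_cd200, cll_kappa, _NEG],
        ),
        "B_cells": _prof(
            "B_cells", 4.70, 4.68, 4.00,
            [_NEG, _POS, 3.8, 3.0, 2.2, 1.4, 4.0, 2.0, _NEG, _NEG],
            modes=(
                (0.6, {"Kappa-FITC": 3.0}),
                (0.4, {"Lambda-PE": 3.0}),
            ),
        ),
        "hematogones": _prof(
            "hematogones", 4.62, 4.60, 3.95,
            [_NEG, _POS, 2.1, 2.5, 3.9, 1.6, 3.0, 2.6, 1.5, 1.5],
        ),
        "T_cells": _prof(
            "T_cells", 4.70, 4.68, 4.00,
            [3.5, _NEG, _NEG, _NEG, 1.8, 3.3, 4.0, 1.6, _NEG, _NEG],
        ),
        "NK_cells": _prof(
            "NK_cells", 4.72, 4.70, 4.05,
            [_NEG, _NEG, _NEG, _NEG, 2.6, 2.2, 4.0, 1.6, _NEG, _NEG],
        ),
        "plasma_cells": _prof(
            "plasma_cells", 4.75, 4.73, 4.10,
            [_NEG, 2.5, _NEG, _NEG, 4.3, 2.8, 2.8, 2.4, 1.4, 1.4],
        ),
        # Monocytes and granulocytes form a partially overlapping continuum
        # (immature/degranulated forms) on SSC, CD45, CD22, CD38 and CD200;
        # both are reported pooled under "Other cell categories".
        "monocytes": _prof(
            "monocytes", 4.88, 4.86, 4.42,
            [_NEG, _NEG, _NEG, 2.35, 2.5, 3.0, 3.9, 2.1, _NEG, _NEG],
            scatter_sd=0.12,
        ),
        "granulocytes": _prof(
            "granulocytes", 4.88, 4.86, 4.66,
            [_NEG, _NEG, _NEG, 1.9, 2.0, 2.8, 3.5, 1.7, _NEG, _NEG],
            scatter_sd=0.12,
        ),
        "erythroblasts": _prof(
            "erythroblasts", 4.50, 4.48, 3.90,
            [_NEG, _NEG, _NEG, _NEG, 1.8, 1.6, _NEG, _NEG, _NEG, _NEG],
        ),
        "basophils_dendritic": _prof(
            "basophils_dendritic", 4.72, 4.70, 4.12,
            [1.6, _NEG, _NEG, 2.8, 2.6, 2.4, 3.5, 2.6, _NEG, _NEG],
        ),
        "blasts": _prof(
            "blasts", 4.80, 4.78, 4.05,
            [_NEG, _NEG, _NEG, 1.8, 3.0, 2.0, 3.0, 1.8, _NEG, _NEG],
        ),
        "debris": _prof(
            "debris", 3.80, 3.78, 3.55,
            [1.0] * 10, scatter_sd=0.22, fluoro_sd=0.40,
        ),
        # Aggregates are generated structurally as doublet sums of two
        # singlet pulses (see _draw_aggregate_events); this template is only
        # the fallback when no singlet mix is available.
        "aggregates": _prof(
            "aggregates", 5.05, 4.60, 4.30,
            [2.5] * 10, scatter_sd=0.09, fluoro_sd=0.50,
        ),
        # Unclassifiable residue: dying cells and lysis debris with smeared
        # scatter and low/dim fluorescence, not a cloud blanketing the
        # defined immunophenotypes (an expert would gate a full phenotype
        # match as that population, never as unknown).
        "unknown": _prof(
            "unknown", 4.20, 4.18, 4.00,
            [1.8] * 10, scatter_sd=0.45, fluoro_sd=0.55,
        ),
    }
    assert set(p) == set(CLASSES)
    return {k: p[k] for k in CLASSES}


def default_class_mix() -> dict[str, float]:
    """Background class prevalences for a typical post-therapy specimen.

    Approximates the relative population sizes of the development test
    split: CLL ~5% of events, T ~10%, aggregates ~7%, debris ~15%, the
    "other" categories forming the majority. Values sum to 1.
    """
    mix = {
        "CLL_cells": 0.052,
        "aggregates": 0.074,
        "B_cells": 0.008,
        "basophils_dendritic": 0.018,
        "blasts": 0.006,
        "debris": 0.151,
        "erythroblasts": 0.030,
        "granulocytes": 0.3704,
        "hematogones": 0.004,
        "monocytes": 0.100,
        "NK_cells": 0.040,
        "plasma_cells": 0.0006,
        "T_cells": 0.106,
        "unknown": 0.040,
    }
    assert abs(sum(mix.values()) - 1.0) < 1e-9
    return mix


# --------------------------------------------------------------------------
# Case generation


@dataclass
class CaseConfig:
    """Configuration for one simulated analysis tube.

    ``class_fractions`` gives the event-level class mix; any shortfall from
    1 is assigned to debris. If ``cll_fraction_of_wbc`` is set, the CLL
    fraction is re-derived as that fraction of the white-cell (non-aggregate,
    non-debris) share and the remaining white-cell classes are rescaled to
    fill the rest, so the configured value is the *expected* CLL %WBC.
    """

    n_events: int = 1_200_000
    class_fractions: dict[str, float] = field(default_factory=default_class_mix)
    cll_fraction_of_wbc: float | None = None
    atypical_cd20_bright: bool = False
    #: SD (log10 units) of the per-case shift of the *CLL clone's* template
    #: locations: each patient's neoplastic phenotype differs slightly, while
    #: normal populations are stereotyped across cases (the premise of
    #: difference-from-normal MRD gating).
    phenotype_jitter_sd: float = 0.08
    #: SD (log10 units) of a per-case, per-channel gain shift shared by all
    #: classes, emulating run-to-run instrument/reagent drift.
    run_gain_sd: float = 0.03
    seed: int = 0
    case_id: str = "case"
    specimen: str = "peripheral_blood"

    def resolved_fractions(self) -> np.ndarray:
        fr = dict(self.class_fractions)
        unknown_keys = set(fr) - set(CLASSES)
        if unknown_keys:
            raise ValueError(f"unknown classes in class_fractions: {sorted(unknown_keys)}")
        vec = np.array([max(fr.get(c, 0.0), 0.0) for c in CLASSES], dtype=float)
        if vec.sum() > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {vec.sum():.4f} > 1")
        vec[CLASSES.index("debris")] += 1.0 - vec.sum()  # remainder -> debris
        if self.cll_fraction_of_wbc is not None:
            f = float(self.cll_fraction_of_wbc)
            if not 0.0 <= f <= 1.0:
                raise ValueError("cll_fraction_of_wbc must be in [0, 1]")
            i_cll = CLASSES.index("CLL_cells")
            excluded = [CLASSES.index(c) for c in WBC_EXCLUDED_CLASSES]
            wbc_share = 1.0 - vec[excluded].sum()
            cll_share = f * wbc_share
            other_wbc = [
                i for i in range(len(CLASSES))
                if i not in excluded and i != i_cll
            ]
            other_sum = vec[other_wbc].sum()
            vec[i_cll] = cll_share
            if other_sum > 0:
                vec[other_wbc] *= (wbc_share - cll_share) / other_sum
        return vec


#: Residual SD (log10) of FSC-H around its pulse-correlated prediction from
#: FSC-A; the area/height ratio of one pulse is tight (~7% CV).
_FSC_RATIO_SD = 0.03

#: Ground-truth consistency margin: an "unknown" draw whose log-intensity
#: profile sits within this many template SDs of a defined class on every
#: fluorescence channel would have been gated as that class by the expert,
#: so it is redrawn.
_UNKNOWN_REJECT_SIGMA = 3.0


def _draw_log_intensities(
    profile: MarkerProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    loc = np.tile(profile.loc, (n, 1))
    if profile.modes:
        weights = np.array([m[0] for m in profile.modes])
        choice = rng.choice(len(profile.modes), size=n, p=weights)
        for m, (_, overrides) in enumerate(profile.modes):
            idx = choice == m
            for ch, v in overrides.items():
                loc[idx, CHANNEL_NAMES.index(ch)] = v
    out = rng.normal(loc, profile.scale[None, :])
    # FSC area and height come from the same pulse: height tracks area with
    # a small residual (singlet A~H; aggregates A >> H by the template's
    # fixed offset). Independent draws would overstate ratio noise and blur
    # doublet discrimination, which on a real instrument is nearly exact.
    out[:, 1] = out[:, 0] - (loc[:, 0] - loc[:, 1]) + rng.normal(
        0.0, _FSC_RATIO_SD, n
    )
    return out


def _mimics_defined_class(
    log10_int: np.ndarray, profiles: Mapping[str, MarkerProfile]
) -> np.ndarray:
    """Events whose fluorescence profile falls inside a defined-class core."""
    hit = np.zeros(len(log10_int), dtype=bool)
    fl = log10_int[:, _FLUORO_SLICE]
    for cls, prof in profiles.items():
        if cls == "unknown":
            continue
        locs = [prof.loc[_FLUORO_SLICE]]
        for _, overrides in prof.modes:
            loc = prof.loc[_FLUORO_SLICE].copy()
            for ch, v in overrides.items():
                loc[CHANNEL_NAMES.index(ch) - 3] = v
            locs.append(loc)
        sd = prof.scale[_FLUORO_SLICE]
        for loc in locs:
            inside = (
                np.abs(fl - loc[None, :]) <= _UNKNOWN_REJECT_SIGMA * sd[None, :]
            ).all(axis=1)
            hit |= inside
    return hit


#: Expert doublet-gate cut on log10(FSC-A) - log10(FSC-H). Singlets sit at
#: ~0.02 +/- 0.03; coincident events above the cut are gated as aggregates,
#: those below are unresolvable from singlets and are gated by phenotype.
_DOUBLET_GATE_RATIO = 0.12


def _draw_aggregate_events(
    n: int,
    rng: np.random.Generator,
    profiles: Mapping[str, MarkerProfile],
    singlet_probs: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Doublets: coincident singlet pairs drawn from the case's singlet mix.

    Pulse areas (FSC-A, SSC-A) and fluorescence signals add linearly; the
    pulse height (FSC-H) is that of the taller component, which is what
    makes FSC-A >> FSC-H the doublet signature. Returns the composite
    intensities and the expert label per event: "aggregates" when the
    pulse ratio exceeds the doublet gate, otherwise the dominant (larger)
    component's class — an expert cannot distinguish a cell plus a speck of
    debris from a singlet and gates it by phenotype.
    """
    classes = [c for c, p in singlet_probs.items() if p > 0]
    probs = np.array([singlet_probs[c] for c in classes])
    probs = probs / probs.sum()
    comp = np.stack(
        [rng.choice(len(classes), size=n, p=probs) for _ in range(2)], axis=1
    )
    linear = np.zeros((n, N_CHANNELS))
    heights = np.zeros((n, 2))
    areas = np.zeros((n, 2))
    for k in range(2):
        for ci, cname in enumerate(classes):
            idx = np.flatnonzero(comp[:, k] == ci)
            if idx.size == 0:
                continue
            lg = _draw_log_intensities(profiles[cname], idx.size, rng)
            lin = np.power(10.0, lg)
            linear[idx] += lin
            heights[idx, k] = lin[:, 1]
            areas[idx, k] = lin[:, 0]
    linear[:, 1] = heights.max(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.log10(linear[:, 0]) - np.log10(linear[:, 1])
    dominant = np.where(areas[:, 0] >= areas[:, 1], comp[:, 0], comp[:, 1])
    labels = np.where(
        ratio > _DOUBLET_GATE_RATIO,
        "aggregates",
        np.asarray(classes, dtype=object)[dominant],
    )
    return linear, labels.astype(object)


def _draw_class_events(
    cls: str,
    n: int,
    rng: np.random.Generator,
    profiles: Mapping[str, MarkerProfile],
    spill: SpilloverMatrix,
    singlet_probs: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if cls == "aggregates" and singlet_probs:
        linear, labels = _draw_aggregate_events(n, rng, profiles, singlet_probs)
        linear[:, _FLUORO_SLICE] = spill.mix(linear[:, _FLUORO_SLICE])
        return np.clip(linear, 0.0, INSTRUMENT_MAX).astype(np.float32), labels
    profile = profiles[cls]
    log10_int = _draw_log_intensities(profile, n, rng)
    if cls == "unknown":
        # Expert ground truth is phenotype-consistent: events matching a
        # defined immunophenotype are never labeled unknown. Resample draws
        # landing inside any defined-class core (bounded number of rounds).
        for _ in range(20):
            bad = _mimics_defined_class(log10_int, profiles)
            if not bad.any():
                break
            log10_int[bad] = _draw_log_intensities(profile, int(bad.sum()), rng)
    linear = np.power(10.0, log10_int)
    linear[:, _FLUORO_SLICE] = spill.mix(linear[:, _FLUORO_SLICE])
    values = np.clip(linear, 0.0, INSTRUMENT_MAX).astype(np.float32)
    return values, np.full(n, cls, dtype=object)


def simulate_case(
    cfg: CaseConfig,
    profiles: Mapping[str, MarkerProfile] | None = None,
    spillover: SpilloverMatrix | None = None,
) -> CaseSample:
    """Simulate one labeled analysis tube.

    Per-class event counts are multinomial over the resolved class
    fractions; intensities follow each class's lognormal template mixed
    through the spillover matrix; events are shuffled into an interleaved
    acquisition order. Deterministic given ``cfg.seed``.
    """
    if cfg.n_events < 0:
        raise ValueError("n_events must be >= 0")
    profiles = profiles or default_profiles(cfg.atypical_cd20_bright)
    spill = spillover or default_spillover()
    fracs = cfg.resolved_fractions()
    rng = np.random.default_rng(cfg.seed)
    gain = rng.normal(0.0, cfg.run_gain_sd, N_CHANNELS) if cfg.run_gain_sd > 0 else 0.0
    clone_shift = (
        rng.normal(0.0, cfg.phenotype_jitter_sd, N_CHANNELS)
        if cfg.phenotype_jitter_sd > 0
        else 0.0
    )
    profiles = {
        cls: replace(
            prof,
            loc=prof.loc + gain + (clone_shift if cls == "CLL_cells" else 0.0),
        )
        for cls, prof in profiles.items()
    }
    counts = rng.multinomial(cfg.n_events, fracs)

    # Doublet components are drawn from the case's own singlet composition.
    singlet_probs = {
        c: float(fr)
        for c, fr in zip(CLASSES, fracs)
        if c != "aggregates" and fr > 0
    }
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for cls, n in zip(CLASSES, counts):
        if n == 0:
            continue
        vals, labs = _draw_class_events(
            cls, int(n), rng, profiles, spill, singlet_probs
        )
        blocks.append(vals)
        labels.append(labs)
    if blocks:
        values = np.vstack(blocks)
        truth = np.concatenate(labels)
        order = rng.permutation(len(truth))
        values, truth = values[order], truth[order]
    else:
        values = np.empty((0, N_CHANNELS), np.float32)
        truth = np.empty(0, dtype=object)

    wbc = int(np.sum(~np.isin(truth.astype(str), list(WBC_EXCLUDED_CLASSES))))
    n_cll = int(np.sum(truth == "CLL_cells"))
    return CaseSample(
        events=EventMatrix(values, PANEL),
        truth=truth.astype(str),
        case_id=cfg.case_id,
        specimen=cfg.specimen,  # type: ignore[arg-type]
        true_cll_fraction=(n_cll / wbc) if wbc else None,
        seed=cfg.seed,
        meta={
            "n_events": int(len(truth)),
            "true_cll_count": n_cll,
            "true_wbc_count": wbc,
            "atypical_cd20_bright": cfg.atypical_cd20_bright,
        },
    )


# --------------------------------------------------------------------------
# Spike-in dilution series


@dataclass
class DilutionPlan:
    """Serial-dilution study: spike donor CLL events into clean backgrounds.

    ``target_fractions`` are clonal fractions of the background's white-cell
    denominator; defaults are the assay's near-threshold levels 0.02%,
    0.002% and 0.001%.
    """

    donor_case: CaseSample
    background_case: CaseSample
    target_fractions: tuple[float, ...] = (2e-4, 2e-5, 1e-5)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.target_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"target fraction {f} must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def spike_dilution(plan: DilutionPlan) -> list[CaseSample]:
    """Generate spiked cases for every (target fraction, replicate) pair.

    The spiked CLL event count is Binomial(background WBC, target fraction);
    spiked events are donor CLL events resampled with replacement. Truth
    labels carry over; the background must contain no CLL truth events.
    """
    donor, bg = plan.donor_case, plan.background_case
    if donor.truth is None or bg.truth is None:
        raise ValueError("dilution requires ground-truth labels on both cases")
    donor_cll = np.flatnonzero(donor.truth == "CLL_cells")
    if donor_cll.size == 0:
        raise ValueError("donor case has no CLL truth events to spike")
    if (bg.truth == "CLL_cells").any():
        raise ValueError("background case must be CLL-free")

    wbc_bg = int(np.sum(~np.isin(bg.truth, list(WBC_EXCLUDED_CLASSES))))
    out: list[CaseSample] = []
    counter = 0
    for target in plan.target_fractions:
        for rep in range(plan.replicates):
            rng = np.random.default_rng(case_seed(plan.seed, counter))
            counter += 1
            n_spike = int(rng.binomial(wbc_bg, target))
            take = rng.choice(donor_cll, size=n_spike, replace=True)
            values = np.vstack([bg.events.values, donor.events.values[take]])
            truth = np.concatenate([bg.truth, np.full(n_spike, "CLL_cells", object)])
            order = rng.permutation(len(truth))
            pct = f"{100 * target:g}pct"
            out.append(
                CaseSample(
                    events=EventMatrix(values[order], bg.events.channels),
                    truth=truth[order].astype(str),
                    case_id=f"{donor.case_id}_spike_{pct}_r{rep}",
                    specimen=bg.specimen,
                    true_cll_fraction=n_spike / (wbc_bg + n_spike) if wbc_bg else None,
                    seed=plan.seed,
                    meta={
                        "target_fraction_of_wbc": target,
                        "replicate": rep,
                        "spiked_cll_count": n_spike,
                        "background_wbc": wbc_bg,
                        "donor_case": donor.case_id,
                    },
                )
            )
    return out


# --------------------------------------------------------------------------
# Cohorts


def case_seed(master_seed: int, index: int) -> int:
    """Per-case seed derivation: ``(master * 1_000_003 + index) mod 2^31``."""
    return int((int(master_seed) * 1_000_003 + int(index)) % (2**31))


def make_cohort(
    n_cases: int,
    mrd_positive_fraction: float,
    low_count_fraction: float,
    seed: int,
    *,
    n_events: int = 1_200_000,
    atypical_high_fraction: float = 0.0,
    low_count_range: tuple[int, int] = (25, 900),
    high_burden_range: tuple[float, float] = (0.005, 0.30),
) -> list[CaseSample]:
    """Simulate a development-style cohort of labeled cases.

    The cohort mixes MRD-negative cases (CLL fraction 0), high-burden
    MRD-positive cases (CLL %WBC log-uniform over ``high_burden_range``)
    and low-count MRD-positive cases whose expected CLL event count is
    uniform over ``low_count_range`` (< 1000 events, the low-count network's
    training stratum). ``atypical_high_fraction`` makes that share of the
    high-burden positives CD20-bright atypical — high-burden by construction,
    so they reach only the full-cohort network's training set.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    for nm, f in [("mrd_positive_fraction", mrd_positive_fraction),
                  ("low_count_fraction", low_count_fraction),
                  ("atypical_high_fraction", atypical_high_fraction)]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1]")

    n_pos = int(round(n_cases * mrd_positive_fraction))
    n_low = int(round(n_pos * low_count_fraction))
    n_high = n_pos - n_low
    n_neg = n_cases - n_pos
    n_atyp = int(round(n_high * atypical_high_fraction))

    rng = np.random.default_rng(case_seed(seed, 10**6))  # cohort-level draws
    mix = default_class_mix()
    wbc_share = 1.0 - mix["aggregates"] - mix["debris"]

    cases: list[CaseSample] = []
    idx = 0

    def _add(cll_frac_wbc: float | None, specimen: str, atypical: bool, kind: str):
        nonlocal idx
        cfg = CaseConfig(
            n_events=n_events,
            cll_fraction_of_wbc=cll_frac_wbc,
            atypical_cd20_bright=atypical,
            seed=case_seed(seed, idx),
            case_id=f"sim{seed}_{idx:03d}_{kind}",
            specimen=specimen,
        )
        case = simulate_case(cfg)
        case.meta["true_mrd_status"] = kind != "neg"
        cases.append(case)
        idx += 1

    specimens = ["peripheral_blood", "bone_marrow"]
    for i in range(n_high):
        lo, hi = high_burden_range
        f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        _add(f, specimens[i % 2], atypical=i < n_atyp,
             kind="high_atyp" if i < n_atyp else "high")
    for i in range(n_low):
        target_count = rng.uniform(*low_count_range)
        # Tiny cases cap the achievable low-count burden well below the
        # low-count threshold.
        f = min(target_count / (n_events * wbc_share), 0.5)
        _add(f, specimens[i % 2], atypical=False, kind="low")
    for i in range(n_neg):
        _add(0.0, specimens[i % 2], atypical=False, kind="neg")
    return cases


def cohort_manifest(cases: Sequence[CaseSample]) -> pd.DataFrame:
    """Tabulate per-case metadata (id, specimen, status, counts, seed)."""
    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "specimen": c.specimen,
                "n_events": c.n_events,
                "true_cll_count": c.meta.get(
                    "true_cll_count",
                    int((c.truth == "CLL_cells").sum()) if c.truth is not None else -1,
                ),
                "true_mrd_status": c.meta.get("true_mrd_status", None),
                "atypical_cd20_bright": c.meta.get("atypical_cd20_bright", False),
                "seed": c.seed,
            }
        )
    return pd.DataFrame(rows)
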