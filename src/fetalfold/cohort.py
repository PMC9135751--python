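"""Cohort simulator: scan records with the statistical structure the
pipeline's models assume.

Two enrollment epochs ("pre" and "pandemic") are simulated with truncated
normal gestational ages, a configurable fraction of mothers scanned twice
(with a 6-12 week gap), fetal sex, maternal age, epoch-shifted distress
scores inside their scale bounds, parental education/employment codes, and
per-scan brain outcomes.

Outcomes are generated from closed-form growth curves — tissue volumes grow
exponentially with gestational age, cortical features linearly — plus a
subject-level random intercept (which induces the within-mother correlation
the repeated-scan models must absorb) and scan-level noise.  Configured
cohort effects are applied additively to tissue volumes and to the folding
amplitude; the folding amplitude drives surface area, gyrification index and
sulcal depth through documented linear sensitivities.  Every scan row also
records the generating phantom parameters (white-matter radius, folding
amplitude) so parameter-recovery tests need no re-derivation, and a
rasterizable :class:`~fetalfold.phantom.PhantomSpec` is attached per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .distress import MEASURES, SCALE_BOUNDS
from .errors import ValidationError
from .phantom import PhantomSpec
from .volume import LOBES, TISSUES

EPOCHS = ("pre", "pandemic")

#: exponential growth-curve coefficients per tissue: volume_cm3 = exp(a + b*GA)
VOLUME_GROWTH: dict[str, tuple[float, float]] = {
    # anchored to ~ (60, 98.5, 15.5, 8.8, 3.95, 1.15) cm^3 at GA 30 with term
    # values inside the physiologic envelope
    "cgm": (0.644, 0.115),
    "wm": (2.040, 0.085),
    "dgm": (0.041, 0.090),
    "cerebellum": (-2.025, 0.140),
    "brainstem": (-1.026, 0.080),
    "hippocampus": (-1.960, 0.070),
}

#: subject-intercept and residual SDs per tissue (cm^3)
VOLUME_SUBJECT_SD: dict[str, float] = {
    "cgm": 5.0, "wm": 7.0, "dgm": 1.2, "cerebellum": 0.9,
    "brainstem": 0.30, "hippocampus": 0.10,
}
VOLUME_RESIDUAL_SD: dict[str, float] = {
    "cgm": 4.0, "wm": 5.0, "dgm": 1.0, "cerebellum": 0.7,
    "brainstem": 0.25, "hippocampus": 0.08,
}

#: folding-amplitude model: amp = AMP_BASE + AMP_GA_SLOPE*(GA-30) + effects
AMP_BASE = 0.10
AMP_GA_SLOPE = 0.004
AMP_SUBJECT_SD = 0.006
AMP_SCAN_SD = 0.004

#: global feature curves: base + ga_slope*GA + amp_sens*(amp - AMP_BASE)
FEATURE_CURVES: dict[str, tuple[float, float, float]] = {
    # name: (base, ga_slope, amplitude sensitivity)
    "area": (4000.0, 400.0, 1.5e5),   # mm^2
    "lgi": (1.00 - 0.009 * 30 + 0.27, 0.009, 8.0),  # ~1.27 at GA 30
    "depth": (0.10, 0.050, 16.0),     # mm
}
FEATURE_RESIDUAL_SD = {"area": 250.0, "lgi": 0.030, "depth": 0.080}
#: fraction of the global value carried by each lobe's area
LOBE_AREA_SHARE = {"frontal": 0.34, "parietal": 0.27, "temporal": 0.22, "occipital": 0.17}
#: additive lobar offsets for LGI / depth
LOBE_OFFSET = {"frontal": 0.02, "parietal": 0.04, "temporal": -0.02, "occipital": -0.04}

PARENTAL_VARS = ("mat_edu", "pat_edu", "mat_empl", "pat_empl")


def _as_epoch_dict(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(EPOCHS) - set(value)
        if missing:
            raise ValidationError(f"{name} missing epochs {sorted(missing)}")
        return {e: float(value[e]) for e in EPOCHS}
    return {e: float(value) for e in EPOCHS}


@dataclass
class CohortSpec:
    """Configuration of one simulated two-epoch cohort.

    Defaults mirror the structure of the study sample this pipeline targets:
    137 + 65 mothers, about a third with a second scan, gestational ages
    truncated to 16.7-39.1 weeks, pandemic-epoch shifts concentrated on the
    stress and depression scales, and pandemic deficits in white-matter,
    cerebellar and hippocampal volumes and in folding amplitude.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"pre": 137, "pandemic": 65}
    )
    repeat_scan_fraction: dict[str, float] | float = field(
        default_factory=lambda: {"pre": 45 / 137, "pandemic": 27 / 65}
    )
    ga_mean: float = 30.5
    ga_sd: float = 6.5
    ga_bounds: tuple[float, float] = (16.7, 39.1)
    scan_gap_weeks: tuple[float, float] = (6.0, 12.0)
    sex_male_fraction: float = 0.52
    maternal_age_mean: float = 34.0
    maternal_age_sd: float = 4.5
    maternal_age_bounds: tuple[float, float] = (17.0, 51.0)
    #: per-epoch (mean, sd) of each distress scale, truncated to scale bounds
    distress_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "pre": {"ssai": (32.0, 10.0), "stai": (33.0, 10.0),
                    "pss": (12.0, 6.5), "epds": (4.5, 4.8)},
            "pandemic": {"ssai": (34.0, 10.5), "stai": (35.0, 10.5),
                         "pss": (15.0, 6.5), "epds": (6.5, 5.2)},
        }
    )
    missing_distress_fraction: float = 29 / 202
    feature_missing_fraction: float = 70 / 274
    #: additive pandemic effect on each tissue volume (cm^3)
    volume_effects: dict[str, float] = field(
        default_factory=lambda: {"wm": -5.8, "cerebellum": -0.5, "hippocampus": -0.1}
    )
    #: additive pandemic effect on the folding amplitude
    fold_amplitude_effect: float = -0.010
    phantom_spacing: tuple[float, float, float] = (1.25, 1.25, 2.0)
    seed: int = 0

    def null(self) -> "CohortSpec":
        """A copy with every cohort effect removed (for calibration runs)."""
        return replace(self, volume_effects={}, fold_amplitude_effect=0.0)

    def validate(self) -> None:
        for e in EPOCHS:
            if self.n_subjects.get(e, 0) < 1:
                raise ValidationError(f"need at least one subject per epoch ({e})")
        for frac_name in ("missing_distress_fraction", "feature_missing_fraction"):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{frac_name} must be in [0, 1]")
        for e, f in _as_epoch_dict(self.repeat_scan_fraction, "repeat_scan_fraction").items():
            if not 0 <= f <= 1:
                raise ValidationError("repeat_scan_fraction must be in [0, 1]")
        lo, hi = self.ga_bounds
        if not lo < hi:
            raise ValidationError("ga_bounds must be increasing")
        self._check_truncation("GA", self.ga_mean, self.ga_sd, lo, hi)
        for e in EPOCHS:
            for m in MEASURES:
                mean, sd = self.distress_params[e][m]
                blo, bhi = SCALE_BOUNDS[m]
                self._check_truncation(f"{m} ({e})", mean, sd, blo, bhi)
        for tissue in self.volume_effects:
            if tissue not in TISSUES:
                raise ValidationError(f"unknown tissue in volume_effects: {tissue!r}")

    @staticmethod
    def _check_truncation(name: str, mean: float, sd: float, lo: float, hi: float) -> None:
        if sd <= 0:
            raise ValidationError(f"{name}: sd must be positive")
        if (lo - mean) / sd > 6 or (mean - hi) / sd > 6:
            raise ValidationError(
                f"{name}: mean {mean} with sd {sd} is impossibly far outside "
                f"the bounds [{lo}, {hi}]"
            )


@dataclass
class SimulatedCohort:
    """Simulation output: scan table, per-scan phantom specs, ground truth."""

    records: pd.DataFrame
    phantom_specs: dict[str, PhantomSpec]
    truth: dict


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def wm_radius_for_ga(ga_weeks: np.ndarray | float) -> np.ndarray | float:
    """White-matter core radius (mm) as a linear function of gestational age."""
    return 8.0 + 0.75 * np.asarray(ga_weeks)


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None, with_phantoms: bool = True
) -> SimulatedCohort:
    """Draw one full cohort; all randomness is fixed by the seed.

    Parameters
    ----------
    spec:
        Cohort configuration; ``spec.seed`` is used unless ``seed`` overrides.
    seed:
        Optional override of ``spec.seed``.
    with_phantoms:
        Attach a :class:`PhantomSpec` per scan (skippable for large
        replicate studies that only use the record table).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.ga_bounds
    gap_lo, gap_hi = spec.scan_gap_weeks
    repeat = _as_epoch_dict(spec.repeat_scan_fraction, "repeat_scan_fraction")

    rows: list[dict] = []
    subj_counter = 0
    for epoch in EPOCHS:
        n = spec.n_subjects[epoch]
        cohort = 0 if epoch == "pre" else 1
        twice = rng.random(n) < repeat[epoch]
        sex = (rng.random(n) < spec.sex_male_fraction).astype(int)
        mat_age = _truncnorm(
            rng, spec.maternal_age_mean, spec.maternal_age_sd,
            *spec.maternal_age_bounds, n,
        )
        # parental codes: identical distributions in both epochs
        edu_p = [0.05, 0.15, 0.25, 0.35, 0.20]
        empl_p = [0.15, 0.10, 0.75]
        mat_edu = rng.choice(np.arange(1, 6), size=n, p=edu_p)
        pat_edu = rng.choice(np.arange(1, 6), size=n, p=edu_p)
        mat_empl = rng.choice(np.arange(1, 4), size=n, p=empl_p)
        pat_empl = rng.choice(np.arange(1, 4), size=n, p=empl_p)
        missing_distress = rng.random(n) < spec.missing_distress_fraction

        # subject-level distress means, then per-scan responses around them
        subj_distress = {}
        for m in MEASURES:
            mean, sd = spec.distress_params[epoch][m]
            blo, bhi = SCALE_BOUNDS[m]
            subj_distress[m] = _truncnorm(rng, mean, sd * 0.85, blo, bhi, n)

        # gestational ages: singletons span the full window; twice-scanned
        # mothers start early enough for the second scan to fit
        ga1 = np.where(
            twice,
            _truncnorm(rng, spec.ga_mean - 5.0, spec.ga_sd, lo, hi - gap_lo, n),
            _truncnorm(rng, spec.ga_mean, spec.ga_sd, lo, hi, n),
        )
        gap = rng.uniform(gap_lo, gap_hi, n)
        ga2 = np.minimum(ga1 + gap, hi - 1e-6)

        subj_intercepts = {
            t: rng.normal(0.0, VOLUME_SUBJECT_SD[t], n) for t in TISSUES
        }
        amp_subj = rng.normal(0.0, AMP_SUBJECT_SD, n)

        for i in range(n):
            subj_counter += 1
            sid = f"S{subj_counter:04d}"
            gas = [ga1[i], ga2[i]] if twice[i] else [ga1[i]]
            for tp, ga in enumerate(gas, start=1):
                row = {
                    "subject_id": sid,
                    "scan_id": f"{sid}_T{tp}",
                    "timepoint": tp,
                    "cohort": cohort,
                    "epoch": epoch,
                    "ga_mri_weeks": float(ga),
                    "sex": int(sex[i]),
                    "maternal_age": float(mat_age[i]),
                    "mat_edu": int(mat_edu[i]),
                    "pat_edu": int(pat_edu[i]),
                    "mat_empl": int(mat_empl[i]),
                    "pat_empl": int(pat_empl[i]),
                    "_subj_idx": i,
                    "_missing_distress": bool(missing_distress[i]),
                }
                for m in MEASURES:
                    if missing_distress[i]:
                        row[m] = np.nan
                    else:
                        blo, bhi = SCALE_BOUNDS[m]
                        mean, sd = spec.distress_params[epoch][m]
                        v = subj_distress[m][i] + rng.normal(0.0, sd * 0.5)
                        row[m] = int(np.clip(np.round(v), blo, bhi))
                # tissue volumes: exponential growth + effect + intercept + noise
                for t in TISSUES:
                    a, b = VOLUME_GROWTH[t]
                    v = (
                        np.exp(a + b * ga)
                        + cohort * spec.volume_effects.get(t, 0.0)
                        + subj_intercepts[t][i]
                        + rng.normal(0.0, VOLUME_RESIDUAL_SD[t])
                    )
                    row[t] = max(v, 0.01)
                # folding amplitude and the features it drives
                amp = (
                    AMP_BASE
                    + AMP_GA_SLOPE * (ga - 30.0)
                    + cohort * spec.fold_amplitude_effect
                    + amp_subj[i]
                    + rng.normal(0.0, AMP_SCAN_SD)
                )
                amp = max(amp, 0.0)
                row["true_fold_amplitude"] = amp
                row["true_wm_radius"] = float(wm_radius_for_ga(ga))
                feature_missing = rng.random() < spec.feature_missing_fraction
                _fill_features(row, rng, ga, amp, feature_missing)
                # hemisphere split of volumes
                share = float(np.clip(rng.normal(0.5, 0.01), 0.45, 0.55))
                for t in TISSUES:
                    row[f"{t}_left"] = row[t] * share
                    row[f"{t}_right"] = row[t] * (1.0 - share)
                rows.append(row)

    records = pd.DataFrame(rows)
    phantom_specs = {}
    if with_phantoms:
        for _, r in records.iterrows():
            phantom_specs[r["scan_id"]] = PhantomSpec.create(
                wm_radius=float(r["true_wm_radius"]),
                fold_amplitude=float(r["true_fold_amplitude"]),
                cgm_thickness=3.0,
                spacing=spec.phantom_spacing,
            )
    truth = {
        "volume_effects": {t: spec.volume_effects.get(t, 0.0) for t in TISSUES},
        "fold_amplitude_effect": spec.fold_amplitude_effect,
        "volume_growth": dict(VOLUME_GROWTH),
    }
    records = records.drop(columns=["_subj_idx", "_missing_distress"])
    return SimulatedCohort(records=records, phantom_specs=phantom_specs, truth=truth)


def _fill_features(row: dict, rng, ga: float, amp: float, missing: bool) -> None:
    """Per-lobe area/LGI/depth columns plus their global combinations."""
    if missing:
        for lobe in (*LOBES, "global"):
            for f in ("area", "lgi", "depth"):
                row[f"{f}_{lobe}"] = np.nan
                for h in ("left", "right"):
                    row[f"{f}_{lobe}_{h}"] = np.nan
        return
    base = {}
    for f, (b0, b_ga, sens) in FEATURE_CURVES.items():
        base[f] = b0 + b_ga * ga + sens * (amp - AMP_BASE)
    lobe_vals: dict[str, dict[str, float]] = {}
    for lobe in LOBES:
        vals = {
            "area": max(
                base["area"] * LOBE_AREA_SHARE[lobe]
                + rng.normal(0.0, FEATURE_RESIDUAL_SD["area"]),
                1.0,
            ),
            "lgi": max(
                base["lgi"] + LOBE_OFFSET[lobe]
                + rng.normal(0.0, FEATURE_RESIDUAL_SD["lgi"]),
                0.5,
            ),
            "depth": max(
                base["depth"] + LOBE_OFFSET[lobe]
                + rng.normal(0.0, FEATURE_RESIDUAL_SD["depth"]),
                0.0,
            ),
        }
        lobe_vals[lobe] = vals
        share = float(np.clip(rng.normal(0.5, 0.01), 0.45, 0.55))
        for f, v in vals.items():
            row[f"{f}_{lobe}"] = v
            if f == "area":
                row[f"{f}_{lobe}_left"] = v * share
                row[f"{f}_{lobe}_right"] = v * (1.0 - share)
            else:
                row[f"{f}_{lobe}_left"] = v + rng.normal(0.0, 0.01)
                row[f"{f}_{lobe}_right"] = v + rng.normal(0.0, 0.01)
    areas = np.array([lobe_vals[l]["area"] for l in LOBES])
    row["area_global"] = float(areas.sum())
    for f in ("lgi", "depth"):
        vals = np.array([lobe_vals[l][f] for l in LOBES])
        row[f"{f}_global"] = float(np.average(vals, weights=areas))
    for h in ("left", "right"):
        ah = np.array([row[f"area_{l}_{h}"] for l in LOBES])
        row[f"area_global_{h}"] = float(ah.sum())
        for f in ("lgi", "depth"):
            vh = np.array([row[f"{f}_{l}_{h}"] for l in LOBES])
            row[f"{f}_global_{h}"] = float(np.average(vh, weights=ah))
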