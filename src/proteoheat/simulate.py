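"""Synthetic DIA-MS dataset generator with a ground-truth registry.

Emulates the measured design of the motivating experiment: 2 tolerance
classes x 2 genotypes per class x 2 sampling days (0 and 6) x 3 biological
replicates = 24 samples, ~30% missing cells overall with intensity-dependent
(MNAR) missingness, plus planted quantitative effects (day, class,
genotype x day interaction) and planted qualitative detection patterns
(binary on/off and switch-like mirror-image proteins).

True (pre-censoring) log2 intensities are additive: per-protein baseline +
planted effects + Gaussian residual noise.  Missingness is logistic
left-censoring on the true log2 intensity,

    P(missing | x) = 1 / (1 + exp(steepness * (x - midpoint))),

so lower-abundance cells are missing more often.  The midpoint is calibrated
at generation time so the realised overall missing fraction matches
``missing_target`` in expectation.  ``mnar_steepness = 0`` selects a pure
MCAR mechanism with per-cell missing probability equal to ``missing_target``
(the degenerate logistic would pin the rate at 0.5 regardless of target).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnnotationSets, IntensityMatrix, SampleDesign


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


DEFAULT_GENOTYPES = (
    ("T1", "tolerant"),
    ("T2", "tolerant"),
    ("S1", "sensitive"),
    ("S2", "sensitive"),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the reference experiment: 24 samples, ~30% missingness,
    planted |log2FC| of 2.0, within-group residual sd of 0.5 log2 units.
    """

    n_proteins: int = 5000
    n_replicates: int = 3
    genotypes: tuple = DEFAULT_GENOTYPES
    days: tuple = (0, 6)
    baseline_mean: float = 20.0   # log2 abundance location
    baseline_sd: float = 2.0      # between-protein spread
    residual_sd: float = 0.5      # within-group noise, log2 units
    n_day_effect: int = 200
    n_class_effect: int = 100
    n_interaction: int = 50
    effect_size_log2fc: float = 2.0
    n_on_off: int = 10
    n_switch_like: int = 10
    missing_target: float = 0.30
    mnar_steepness: float = 1.0
    mnar_midpoint: float | None = None  # None -> calibrated to missing_target
    switch_noise_prob: float = 0.0      # prob. of flipping one replicate per pattern cell
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_replicates": self.n_replicates,
            "n_day_effect": self.n_day_effect,
            "n_class_effect": self.n_class_effect,
            "n_interaction": self.n_interaction,
            "n_on_off": self.n_on_off,
            "n_switch_like": self.n_switch_like,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        planted = (
            self.n_day_effect + self.n_class_effect + self.n_interaction
            + self.n_on_off + self.n_switch_like
        )
        if planted > self.n_proteins:
            raise ConfigError(
                f"planted effect counts sum to {planted} > n_proteins={self.n_proteins}"
            )
        if not (0.0 <= self.missing_target < 1.0):
            raise ConfigError(f"missing_target must be in [0, 1), got {self.missing_target}")
        classes = {c for _, c in self.genotypes}
        if self.n_class_effect or self.n_interaction or self.n_on_off or self.n_switch_like:
            if len(classes) < 2:
                raise ConfigError("class/interaction/pattern effects need >= 2 tolerance classes")
        if len(self.days) < 2 and (self.n_day_effect or self.n_interaction or self.n_switch_like):
            raise ConfigError("day-dependent effects need >= 2 sampling days")


@dataclass
class TruthRegistry:
    """Ground truth for planted effects, for recovery tests.

    ``table`` has one row per planted protein with columns: protein_id,
    effect_kind (day | class | interaction | on_off | switch_like),
    true_log2fc (NaN for detection patterns) and affected_groups (a short
    human-readable description of which cells carry the effect/pattern).
    ``true_values`` holds the full pre-censoring log2 matrix — the internal
    truth used to assert the MNAR direction of the censoring.
    """

    table: pd.DataFrame
    true_values: pd.DataFrame = field(repr=False, default=None)

    def ids(self, kind: str) -> list:
        sel = self.table["effect_kind"] == kind
        return list(self.table.loc[sel, "protein_id"])


# --------------------------------------------------------------------------

def _build_design(config: SimConfig) -> SampleDesign:
    rows = []
    for (geno, klass), day, rep in itertools.product(
        config.genotypes, config.days, range(1, config.n_replicates + 1)
    ):
        sid = f"{geno}_d{day}_r{rep}"
        rows.append((sid, geno, klass, day, rep))
    df = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "tolerance_class", "day", "replicate"]
    ).set_index("sample_id")
    return SampleDesign(df)


def _calibrate_midpoint(x: np.ndarray, steepness: float, target_mean_p: float) -> float:
    """Bisect for the logistic midpoint giving the requested mean missing probability."""
    lo, hi = x.min() - 40.0, x.max() + 40.0

    def mean_p(mid):
        return float(np.mean(1.0 / (1.0 + np.exp(steepness * (x - mid)))))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target_mean_p:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


def generate_dataset(config: SimConfig) -> tuple[IntensityMatrix, SampleDesign, TruthRegistry]:
    """Generate an intensity matrix, its design, and the truth registry.

    Deterministic given the config (including seed).  Returns the matrix on
    the log2 scale with ``scale_flag="raw"`` semantics deliberately *not*
    used: the generator emits log2 values directly (``scale_flag="log2"``)
    since the whole analysis is log2-based; write/read round-trips preserve
    values and mask.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _build_design(config)
    samples = design.sample_ids
    n, m = config.n_proteins, len(samples)

    protein_ids = [f"PROT{i:05d}" for i in range(1, n + 1)]
    klass = design.table["tolerance_class"].to_numpy()
    day = design.table["day"].to_numpy()
    classes = sorted(set(klass))
    stress_day = max(config.days)
    is_stress = day == stress_day

    # additive true signal on log2 scale
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    true = baseline[:, None] + rng.normal(0.0, config.residual_sd, size=(n, m))

    # assign planted proteins: mutually exclusive blocks at the top of the matrix
    idx = iter(range(n))
    day_idx = [next(idx) for _ in range(config.n_day_effect)]
    class_idx = [next(idx) for _ in range(config.n_class_effect)]
    inter_idx = [next(idx) for _ in range(config.n_interaction)]
    onoff_idx = [next(idx) for _ in range(config.n_on_off)]
    switch_idx = [next(idx) for _ in range(config.n_switch_like)]

    records = []
    eff = config.effect_size_log2fc

    for i in day_idx:
        sign = rng.choice([-1.0, 1.0])
        true[i, is_stress] += sign * eff
        records.append((protein_ids[i], "day", sign * eff,
                        f"day{stress_day} all classes"))
    for i in class_idx:
        sign = rng.choice([-1.0, 1.0])
        in_class = klass == classes[-1]  # 'tolerant' sorts after 'sensitive'
        true[i, in_class] += sign * eff
        records.append((protein_ids[i], "class", sign * eff,
                        f"{classes[-1]} both days"))
    for i in inter_idx:
        sign = rng.choice([-1.0, 1.0])
        cell = (klass == classes[-1]) & is_stress
        true[i, cell] += sign * eff
        records.append((protein_ids[i], "interaction", sign * eff,
                        f"{classes[-1]} day{stress_day} only"))

    # deterministic detection patterns; these cells bypass stochastic censoring
    forced_missing = np.zeros((n, m), dtype=bool)
    forced_observed = np.zeros((n, m), dtype=bool)
    for i in onoff_idx:
        on_class = rng.choice(classes)
        on = klass == on_class
        forced_observed[i, on] = True
        forced_missing[i, ~on] = True
        records.append((protein_ids[i], "on_off", np.nan, f"on in {on_class} both days"))
    for i in switch_idx:
        high_class = rng.choice(classes)
        in_high = klass == high_class
        # high class: detected at baseline, missing at stress day; other class inverse
        forced_observed[i, in_high & ~is_stress] = True
        forced_missing[i, in_high & is_stress] = True
        forced_missing[i, ~in_high & ~is_stress] = True
        forced_observed[i, ~in_high & is_stress] = True
        records.append((protein_ids[i], "switch_like", np.nan,
                        f"{high_class} high at day {min(config.days)}"))

    if config.switch_noise_prob > 0:
        pattern_rows = np.array(onoff_idx + switch_idx, dtype=int)
        for i in pattern_rows:
            for cell_sel in _pattern_cells(klass, day):
                if rng.random() < config.switch_noise_prob:
                    j = rng.choice(np.flatnonzero(cell_sel))
                    forced_missing[i, j], forced_observed[i, j] = (
                        forced_observed[i, j], forced_missing[i, j])

    # stochastic censoring on everything not governed by a planted pattern
    censorable = ~(forced_missing | forced_observed)
    missing = forced_missing.copy()
    if config.missing_target > 0 and censorable.any():
        total = n * m
        want = config.missing_target * total - forced_missing.sum()
        target_p = want / censorable.sum()
        if target_p < 0:
            target_p = 0.0
        x = true[censorable]
        if config.mnar_steepness == 0:
            p = np.full(x.shape, min(target_p, 1.0))
        else:
            mid = (config.mnar_midpoint if config.mnar_midpoint is not None
                   else _calibrate_midpoint(x, config.mnar_steepness, target_p))
            p = 1.0 / (1.0 + np.exp(config.mnar_steepness * (x - mid)))
        missing[censorable] = rng.random(x.shape) < p

    values = np.where(missing, np.nan, true)
    values_df = pd.DataFrame(values, index=protein_ids, columns=samples)
    true_df = pd.DataFrame(true, index=protein_ids, columns=samples)
    matrix = IntensityMatrix(values_df, values_df.notna(), scale_flag="log2")

    reg = pd.DataFrame(
        records, columns=["protein_id", "effect_kind", "true_log2fc", "affected_groups"]
    )
    return matrix, design, TruthRegistry(table=reg, true_values=true_df)


def _pattern_cells(klass: np.ndarray, day: np.ndarray):
    """Iterate boolean selectors for each (class, day) cell."""
    for c in sorted(set(klass)):
        for d in sorted(set(day)):
            yield (klass == c) & (day == d)


# --------------------------------------------------------------------------
# microclimate
# --------------------------------------------------------------------------

def generate_microclimate(
    days: int = 7,
    ck_temp_mean: float = 30.0,
    ehs_delta: float = 4.9,
    rh_profile=60.0,
    diurnal_amplitude: float = 6.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    start: str = "2025-07-20",
) -> pd.DataFrame:
    """Paired control (CK) and enclosure (EHS) logger series at 30-min cadence.

    Temperature follows a sinusoidal diurnal cycle peaking at 14:00 around
    ``ck_temp_mean``; the enclosure series is offset by ``ehs_delta`` degC
    plus Gaussian logger noise.  ``rh_profile`` is either a scalar relative
    humidity (%) or a length-48 within-day series; values must lie in
    [0, 100].  Returns a tidy frame with columns timestamp, treatment,
    temperature_c, relative_humidity.
    """
    rh = np.asarray(rh_profile, dtype=float)
    if rh.ndim == 0:
        rh = np.full(48, float(rh))
    if rh.shape != (48,):
        raise ConfigError("rh_profile must be scalar or a length-48 daily series")
    if rh.min() < 0 or rh.max() > 100:
        raise ConfigError("relative humidity must lie in [0, 100]")

    rng = np.random.default_rng(seed)
    stamps = pd.date_range(start=start, periods=days * 48, freq="30min")
    hours = stamps.hour + stamps.minute / 60.0
    diurnal = diurnal_amplitude * np.sin(2 * np.pi * (hours - 8.0) / 24.0)
    t_ck = ck_temp_mean + diurnal + rng.normal(0.0, noise_sd, len(stamps))
    t_ehs = ck_temp_mean + diurnal + ehs_delta + rng.normal(0.0, noise_sd, len(stamps))
    rh_series = np.tile(rh, days)
    frames = []
    for name, temp in (("CK", t_ck), ("EHS", t_ehs)):
        frames.append(pd.DataFrame({
            "timestamp": stamps,
            "treatment": name,
            "temperature_c": temp,
            "relative_humidity": rh_series,
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# pathway annotation and physiological traits
# --------------------------------------------------------------------------

def generate_annotations(
    protein_ids,
    registry: TruthRegistry | None = None,
    n_sets: int = 30,
    set_size_range: tuple = (10, 60),
    n_planted_sets: int = 3,
    planted_fraction: float = 0.8,
    seed: int = 0,
) -> AnnotationSets:
    """Random GMT-style pathway sets, optionally enriched for planted proteins.

    ``n_planted_sets`` pathways draw ``planted_fraction`` of their members
    from the registry's day-effect proteins, giving the enrichment stage a
    real signal to find; the rest are uniform draws from the full id list.
    """
    rng = np.random.default_rng(seed)
    ids = list(protein_ids)
    names, members = {}, {}
    planted_pool = registry.ids("day") if registry is not None else []
    for s in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(ids))
        if s < n_planted_sets and planted_pool:
            k_planted = min(int(round(planted_fraction * size)), len(planted_pool))
            chosen = list(rng.choice(planted_pool, size=k_planted, replace=False))
            rest = rng.choice(ids, size=size - k_planted, replace=False)
            mem = set(chosen) | set(rest)
            desc = "synthetic planted pathway"
        else:
            mem = set(rng.choice(ids, size=size, replace=False))
            desc = "synthetic background pathway"
        pid = f"SET{s:03d}"
        names[pid] = desc
        members[pid] = mem
    return AnnotationSets(names=names, members=members)


TRAIT_BASELINES = {
    # trait: (baseline level, unit, class effect on tolerant, per-day-late change)
    "chlorophyll": (2.5, "mg/g FW", +0.5, -0.08),
    "POD": (120.0, "U/g FW", +5.0, +8.0),
    "MDA": (8.0, "nmol/g FW", -0.5, +0.9),
}


def generate_traits(
    days: tuple = (3, 9),
    n_replicates: int = 3,
    genotypes: tuple = DEFAULT_GENOTYPES,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Physiological trait table (chlorophyll, POD, MDA) under stress.

    Chlorophyll declines with exposure time but stays higher in the tolerant
    class; POD activity and MDA rise with time with weaker class effects —
    the qualitative structure reported for enclosure heat-stress assays.
    Tidy output: genotype, tolerance_class, day, replicate, trait, value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trait, (base, _unit, class_eff, day_eff) in TRAIT_BASELINES.items():
        for geno, klass in genotypes:
            for day in days:
                mu = base + (class_eff if klass == "tolerant" else 0.0) + day_eff * day
                for rep in range(1, n_replicates + 1):
                    val = mu * (1.0 + rng.normal(0.0, noise_frac))
                    rows.append((geno, klass, day, rep, trait, val))
    return pd.DataFrame(
        rows, columns=["genotype", "tolerance_class", "day", "replicate", "trait", "value"]
    )
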