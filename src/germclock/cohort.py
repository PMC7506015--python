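"""Synthetic stratified cohort and array-like sperm methylome generator.

Emulates a study design in which participants are stratified into four
narrow age categories, each split into normal-BMI and high/obese-BMI
sub-categories of equal size, and assayed on a genome-wide methylation
array. The methylome is generated on the M-value (log2-logit) scale:

    M_ij = mu_j + a_j * epigenetic_age_i + eps_ij,   eps ~ N(0, noise_sd^2)

where the age slope ``a_j`` is nonzero only for CpGs inside designated
"clock" regions, and ``epigenetic_age = age + bmi_acceleration_years``
for high-BMI participants. Beta values are the inverse logit of M. A
dedicated marker region (14 CpGs, DLK1-like) is kept essentially
unmethylated in sperm and highly methylated in the somatic contamination
profile, so that sample purity can be screened downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "SimulationParams",
    "RegionMap",
    "GroundTruth",
    "DEFAULT_DESIGN",
    "generate_cohort",
    "simulate_methylome",
    "spike_contamination",
    "MARKER_REGION_ID",
]

MARKER_REGION_ID = "DLK1_like"

# open-interval clamp for beta values so the logit stays finite
BETA_FLOOR = 1e-6


class ConfigurationError(ValueError):
    """Invalid study design or simulation parameters."""


@dataclass(frozen=True)
class CohortDesign:
    """Stratified age x BMI study design.

    ``age_categories`` and ``bmi_subcategories`` are ``(label, low, high)``
    triples; ages in years, BMI in kg/m^2. Every (age, BMI) cell receives
    exactly ``n_per_cell`` participants.
    """

    age_categories: tuple = (
        ("22-24", 22.0, 24.0),
        ("30", 30.0, 31.0),
        ("40-41", 40.0, 41.0),
        (">48", 48.0, 70.0),
    )
    bmi_subcategories: tuple = (
        ("normal", 18.5, 24.9),
        ("high", 30.0, 42.0),
    )
    n_per_cell: int = 12

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ConfigurationError("n_per_cell must be >= 1")
        for name, cats in (("age", self.age_categories), ("bmi", self.bmi_subcategories)):
            prev_hi = -np.inf
            for label, lo, hi in cats:
                if lo > hi:
                    raise ConfigurationError(f"{name} category {label!r}: low > high")
                if lo < prev_hi:
                    raise ConfigurationError(f"{name} category intervals overlap at {label!r}")
                prev_hi = hi

    @property
    def n_samples(self) -> int:
        return len(self.age_categories) * len(self.bmi_subcategories) * self.n_per_cell


DEFAULT_DESIGN = CohortDesign()


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the methylome generator.

    n_cpgs: CpGs outside the marker region; grouped into consecutive
        regions of ``cpgs_per_region`` (last region keeps the remainder).
    n_clock_regions: regions carrying a shared nonzero age slope.
    baseline_logit_mean_sd: mean/SD of per-CpG intercepts, M units.
    age_slope_sd: SD of the per-region age slope, M units per year.
    bmi_acceleration_years: extra epigenetic years injected into every
        high-BMI participant (the age-acceleration effect under test).
    noise_sd: per-CpG residual SD, M units.
    contamination_fraction: somatic admixture applied by the pipeline
        to designated samples (0 = pure sperm).
    """

    n_cpgs: int = 6000
    cpgs_per_region: int = 100
    n_clock_regions: int = 51
    baseline_logit_mean_sd: tuple = (0.0, 2.0)
    age_slope_sd: float = 0.0012
    bmi_acceleration_years: float = 1.4
    noise_sd: float = 0.5
    contamination_fraction: float = 0.0
    marker_cpgs: int = 14
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ConfigurationError("contamination_fraction must lie in [0, 1]")
        n_regions = max(1, self.n_cpgs // self.cpgs_per_region)
        if self.n_clock_regions > n_regions:
            raise ConfigurationError(
                f"n_clock_regions={self.n_clock_regions} exceeds the "
                f"{n_regions} regions implied by n_cpgs/cpgs_per_region"
            )


@dataclass
class RegionMap:
    """Named regions, each a list of member CpG probe ids."""

    regions: dict  # region_id -> list of probe ids
    clock_regions: list = field(default_factory=list)
    marker_region: str | None = None

    def probes(self, region_id: str) -> list:
        return self.regions[region_id]

    @property
    def region_ids(self) -> list:
        return list(self.regions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, probes in self.regions.items():
            flags = []
            if rid in self.clock_regions:
                flags.append("clock")
            if rid == self.marker_region:
                flags.append("marker")
            rows.append((rid, ",".join(probes), ";".join(flags) or "."))
        return pd.DataFrame(rows, columns=["region_id", "probes", "flags"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionMap":
        regions, clock, marker = {}, [], None
        for _, row in df.iterrows():
            rid = row["region_id"]
            regions[rid] = row["probes"].split(",")
            flags = set(str(row["flags"]).split(";"))
            if "clock" in flags:
                clock.append(rid)
            if "marker" in flags:
                marker = rid
        return cls(regions=regions, clock_regions=clock, marker_region=marker)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks.

    cpg_effects: per-CpG intercept/slope table (probe_id, region_id,
        intercept, age_slope, is_clock, is_marker).
    sample_truth: per-sample chronological and injected epigenetic age.
    somatic_beta: beta profile of the contaminating somatic signal.
    """

    cpg_effects: pd.DataFrame
    sample_truth: pd.DataFrame
    clock_region_ids: list
    marker_region_id: str
    somatic_beta: pd.Series


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(design: CohortDesign = DEFAULT_DESIGN, seed: int = 0) -> pd.DataFrame:
    """Draw a stratified cohort table.

    Ages and BMIs are uniform within each cell's interval. Semen
    parameters are cosmetic draws near published clinic values and never
    feed any downstream computation; concentration respects the
    eligibility floor of 10 million sperm/ml.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for age_label, age_lo, age_hi in design.age_categories:
        for bmi_label, bmi_lo, bmi_hi in design.bmi_subcategories:
            for _ in range(design.n_per_cell):
                i += 1
                rows.append(
                    {
                        "id": f"S{i:03d}",
                        "age": rng.uniform(age_lo, age_hi),
                        "bmi": rng.uniform(bmi_lo, bmi_hi),
                        "age_category": age_label,
                        "bmi_category": bmi_label,
                        "progressive_motility": float(np.clip(rng.normal(46.0, 10.0), 5.0, 90.0)),
                        "concentration": float(np.clip(rng.lognormal(np.log(70.0), 0.4), 10.0, 400.0)),
                        "viability": float(np.clip(rng.normal(53.0, 8.0), 10.0, 95.0)),
                    }
                )
    return pd.DataFrame(rows)


def _build_region_map(params: SimulationParams) -> tuple[RegionMap, list]:
    probe_ids = [f"cg{j:06d}" for j in range(params.n_cpgs)]
    regions = {}
    step = params.cpgs_per_region
    r = 0
    for start in range(0, params.n_cpgs, step):
        chunk = probe_ids[start : start + step]
        # fold a short tail into the previous region rather than creating a stub
        if len(chunk) < step and r > 0:
            regions[f"R{r - 1:04d}"].extend(chunk)
        else:
            regions[f"R{r:04d}"] = chunk
            r += 1
    clock = [f"R{k:04d}" for k in range(params.n_clock_regions)]
    marker_probes = [f"cgM{j:04d}" for j in range(params.marker_cpgs)]
    regions[MARKER_REGION_ID] = marker_probes
    rmap = RegionMap(regions=regions, clock_regions=clock, marker_region=MARKER_REGION_ID)
    return rmap, probe_ids + marker_probes


def simulate_methylome(
    cohort: pd.DataFrame,
    params: SimulationParams = SimulationParams(),
    seed: int | None = None,
    truth: GroundTruth | None = None,
):
    """Generate a beta matrix (probes x samples) with known ground truth.

    Returns ``(beta, region_map, truth)``. If an existing ``truth`` is
    passed, its CpG intercepts/slopes are reused and only the residual
    noise is redrawn — this produces a second cohort measured on the
    "same array", e.g. an independent evaluation cohort for a clock
    trained elsewhere.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if seed is None:
        seed = params.seed
    rng_mu, rng_slope, rng_noise = _rng_streams(seed, 3)

    region_map, all_probes = _build_region_map(params)

    if truth is None:
        mu_mean, mu_sd = params.baseline_logit_mean_sd
        mu = rng_mu.normal(mu_mean, mu_sd, size=params.n_cpgs)
        # one slope per clock region, shared by its member CpGs: regional
        # methylation drifts coherently with age
        slopes = np.zeros(params.n_cpgs)
        region_slopes = rng_slope.normal(0.0, params.age_slope_sd, size=params.n_clock_regions)
        probe_region = {}
        for rid, probes in region_map.regions.items():
            for p in probes:
                probe_region[p] = rid
        clock_set = dict(zip(region_map.clock_regions, region_slopes))
        for j, p in enumerate(all_probes[: params.n_cpgs]):
            rid = probe_region[p]
            if rid in clock_set:
                slopes[j] = clock_set[rid]
        # marker CpGs: essentially unmethylated in sperm, no age effect
        marker_mu = np.full(params.marker_cpgs, np.log2(0.005 / 0.995))
        intercepts = np.concatenate([mu, marker_mu])
        all_slopes = np.concatenate([slopes, np.zeros(params.marker_cpgs)])
        effects = pd.DataFrame(
            {
                "probe_id": all_probes,
                "region_id": [probe_region[p] for p in all_probes],
                "intercept": intercepts,
                "age_slope": all_slopes,
            }
        )
        effects["is_clock"] = effects["region_id"].isin(region_map.clock_regions)
        effects["is_marker"] = effects["region_id"] == MARKER_REGION_ID
        somatic = pd.Series(_inv_logit2(intercepts), index=all_probes, name="somatic_beta")
        # fully methylated at the marker locus in somatic DNA: any 50/50 mix
        # with (positive) sperm beta lands strictly above the 0.5 screen
        somatic.loc[effects.loc[effects["is_marker"], "probe_id"]] = 1.0
    else:
        effects = truth.cpg_effects
        if list(effects["probe_id"]) != all_probes:
            raise ConfigurationError("supplied truth does not match the probe layout of params")
        somatic = truth.somatic_beta

    high = (cohort["bmi_category"] == "high").to_numpy()
    epi_age = cohort["age"].to_numpy() + params.bmi_acceleration_years * high

    mu_vec = effects["intercept"].to_numpy()
    a_vec = effects["age_slope"].to_numpy()
    m = mu_vec[:, None] + a_vec[:, None] * epi_age[None, :]
    if params.noise_sd > 0:
        m = m + rng_noise.normal(0.0, params.noise_sd, size=m.shape)
    beta_vals = np.clip(_inv_logit2(m), BETA_FLOOR, 1.0 - BETA_FLOOR)

    beta = pd.DataFrame(beta_vals, index=pd.Index(all_probes, name="probe_id"), columns=list(cohort["id"]))
    sample_truth = pd.DataFrame(
        {"id": cohort["id"].to_numpy(), "age": cohort["age"].to_numpy(), "epigenetic_age": epi_age}
    )
    out_truth = GroundTruth(
        cpg_effects=effects,
        sample_truth=sample_truth,
        clock_region_ids=list(region_map.clock_regions),
        marker_region_id=MARKER_REGION_ID,
        somatic_beta=somatic,
    )
    return beta, region_map, out_truth


def _inv_logit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def spike_contamination(
    beta: pd.DataFrame,
    sample_ids: list,
    fraction: float,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Mix a somatic beta profile into selected samples.

    Models incomplete somatic-cell lysis: the observed beta becomes
    ``(1 - fraction) * sperm + fraction * somatic``. Marker-region CpGs
    in the somatic profile are near fully methylated, so contaminated
    samples light up in the purity screen.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    missing = [s for s in sample_ids if s not in beta.columns]
    if missing:
        raise KeyError(f"unknown sample ids: {missing}")
    out = beta.copy()
    if fraction == 0.0 or not sample_ids:
        return out
    somatic = truth.somatic_beta.reindex(beta.index).to_numpy()
    for s in sample_ids:
        mixed = (1.0 - fraction) * out[s].to_numpy() + fraction * somatic
        out[s] = np.clip(mixed, BETA_FLOOR, 1.0 - BETA_FLOOR)
    return out


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def truth_to_csv(truth: GroundTruth, effects_path, samples_path) -> None:
    truth.cpg_effects.to_csv(effects_path, index=False)
    truth.sample_truth.to_csv(samples_path, index=False)


def replace_params(params: SimulationParams, **kwargs) -> SimulationParams:
    return dataclasses.replace(params, **kwargs)
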