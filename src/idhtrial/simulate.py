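"""Synthetic-cohort generator.

Emulates the statistical structure of the perioperative trial so every
downstream stage (evaluability filter, borrowing model, response evaluation,
pharmacodynamic associations) runs offline:

* arm assignment following the study's randomization (cohort 1 at 2:2:1 to
  ivosidenib 500 mg q.d. / vorasidenib 50 mg q.d. / no treatment; cohort 2 at
  1:1 to ivosidenib 250 mg b.i.d. / vorasidenib 10 mg q.d.);
* tumor 2-HG drawn per arm from base-10 lognormals moment-matched to the
  arithmetic means and s.d.s each arm reports (the borrowing model works on
  log10 2-HG, so the lognormal is the natural generative family);
* biomarkers (Ki-67, 5hmC%, CD3/CD8 densities) linearly coupled to log10 2-HG
  with Gaussian noise, truncated at zero;
* an expression matrix with a planted 2-HG-associated gene signature;
* per-subject SPD lesion series with multiplicative drift.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Arm, ExternalControlRecord, SubjectRecord

__all__ = [
    "ArmSpec",
    "LognormalParams",
    "BiomarkerCoupling",
    "ExpressionSpec",
    "SpdSpec",
    "GeneratorConfig",
    "moment_match_lognormal",
    "simulate_cohort",
    "simulate_biomarkers",
    "simulate_expression",
    "simulate_spd_series",
    "write_expression_matrix",
    "read_expression_matrix",
    "write_gmt",
    "read_gmt",
    "DEFAULT_CONFIG",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ArmSpec:
    """Target arithmetic moments (µg g⁻¹) and size for one arm's tumor 2-HG."""

    label: str
    n: int
    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.target_mean <= 0:
            raise ValueError("target_mean must be positive")
        if self.target_sd < 0:
            raise ValueError("target_sd must be nonnegative")


@dataclass(frozen=True)
class LognormalParams:
    """Base-10 lognormal: log10(X) ~ Normal(location, scale²)."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")


def moment_match_lognormal(mean: float, sd: float) -> LognormalParams:
    """Base-10 lognormal whose *arithmetic* mean and s.d. equal the inputs.

    With cv² = sd²/mean²:  scale² = ln(1 + cv²)/ln²(10) and
    location = log10(mean) − (ln 10 / 2)·scale².  For sd = 0 the distribution
    degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    cv2 = (sd / mean) ** 2
    scale2 = math.log1p(cv2) / _LN10**2
    location = math.log10(mean) - 0.5 * _LN10 * scale2
    return LognormalParams(location=location, scale=math.sqrt(scale2))


@dataclass(frozen=True)
class BiomarkerCoupling:
    """Linear link of one biomarker to log10 2-HG: value = intercept + slope·x + noise."""

    slope: float
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted-signature expression matrix: n_genes total, the first
    n_signature_genes linear in the z-scored covariate with the given
    per-gene effect (log2 units per z unit) and residual s.d."""

    n_genes: int = 2000
    n_signature_genes: int = 50
    effect: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes must not exceed n_genes")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("spreads must be nonnegative")


@dataclass(frozen=True)
class SpdSpec:
    """Postoperative SPD trajectories: baseline lognormal, per-visit
    multiplicative drift (e.g. −0.10 shrinks 10% per visit) with lognormal
    noise; ``no_residual_fraction`` of subjects resect completely."""

    baseline_mean: float = 8.0
    baseline_sd: float = 4.0
    drift_per_visit: float = -0.05
    noise_sd: float = 0.05
    n_visits: int = 6
    visit_interval_days: int = 56
    no_residual_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.no_residual_fraction <= 1.0):
            raise ValueError("no_residual_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.drift_per_visit <= -1.0:
            raise ValueError("drift_per_visit must exceed -1")


# Printed per-arm summaries (arithmetic mean, s.d., µg g⁻¹) and evaluable sizes.
_DEFAULT_ARMS = (
    ArmSpec("VOR50", 11, 8.9, 4.1),
    ArmSpec("VOR10", 7, 67.5, 65.4),
    ArmSpec("IVO500", 10, 20.9, 30.7),
    ArmSpec("IVO250", 7, 16.8, 18.1),
    ArmSpec("CTRL_INTERNAL", 5, 154.9, 146.9),
    ArmSpec("CTRL_EXTERNAL", 61, 276.8, 231.4),
    ArmSpec("CTRL_EXTERNAL_WT", 20, 3.7, 3.1),
)

_DEFAULT_COUPLING = {
    # slope per log10 unit of 2-HG; intercepts at typical on-treatment levels
    "ki67_pct": BiomarkerCoupling(slope=3.0, intercept=2.0, noise_sd=2.0),
    "hmc5_pct": BiomarkerCoupling(slope=-0.04, intercept=0.15, noise_sd=0.02),
    "cd3_density": BiomarkerCoupling(slope=-60.0, intercept=260.0, noise_sd=80.0),
    "cd8_density": BiomarkerCoupling(slope=-25.0, intercept=110.0, noise_sd=40.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic trial needs; defaults are the study conditions."""

    arms: tuple[ArmSpec, ...] = _DEFAULT_ARMS
    # realized exclusion counts were 2/3/4 of 49; flags drawn as independent Bernoulli
    p_insufficient_tissue: float = 2 / 49
    p_midh1_not_confirmed: float = 3 / 49
    p_incorrect_dosing: float = 4 / 49
    p_missed_doses: float = 0.0
    coupling: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    expression: ExpressionSpec = ExpressionSpec()
    spd: SpdSpec = SpdSpec()

    def arm(self, label: str) -> ArmSpec:
        for spec in self.arms:
            if spec.label == label:
                return spec
        raise KeyError(label)


DEFAULT_CONFIG = GeneratorConfig()

_ARM_COHORT = {"VOR50": 1, "IVO500": 1, "CTRL_INTERNAL": 1, "VOR10": 2, "IVO250": 2}


def _draw_2hg(rng: np.random.Generator, spec: ArmSpec) -> np.ndarray:
    params = moment_match_lognormal(spec.target_mean, spec.target_sd)
    log10_values = params.location + params.scale * rng.standard_normal(spec.n)
    return 10.0 ** log10_values


def simulate_cohort(
    config: GeneratorConfig = DEFAULT_CONFIG, seed: int = 0
) -> tuple[list[SubjectRecord], list[ExternalControlRecord]]:
    """Generate one synthetic trial: enrolled subjects plus external controls.

    Arm sizes follow the configured :class:`ArmSpec` counts; 2-HG comes from
    the moment-matched lognormal of each arm; eligibility flags are drawn as
    independent Bernoulli at the configured rates (dosing flags only for
    treated subjects); biomarkers and lesion series are attached per subject.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    externals: list[ExternalControlRecord] = []
    sid = 0
    for spec in config.arms:
        values = _draw_2hg(rng, spec)
        if spec.label == "CTRL_EXTERNAL":
            externals.extend(
                ExternalControlRecord(f"EXT{i + 1:03d}", "mIDH1", float(v))
                for i, v in enumerate(values)
            )
            continue
        if spec.label == "CTRL_EXTERNAL_WT":
            externals.extend(
                ExternalControlRecord(f"EXTWT{i + 1:03d}", "WT", float(v))
                for i, v in enumerate(values)
            )
            continue
        arm = Arm("UNTREATED" if spec.label == "CTRL_INTERNAL" else spec.label)
        for value in values:
            sid += 1
            treated = arm.treated
            log10_2hg = math.log10(value)
            bio = simulate_biomarkers(log10_2hg, config, rng=rng)
            series = simulate_spd_series(config, rng=rng)
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{sid:03d}",
                    cohort=_ARM_COHORT[spec.label],
                    arm=arm,
                    treated_presurgery=treated,
                    missed_doses_2wk=int(rng.random() < config.p_missed_doses) * 2
                    if treated else 0,
                    midh1_confirmed=not rng.random() < config.p_midh1_not_confirmed,
                    tissue_sufficient=not rng.random() < config.p_insufficient_tissue,
                    dosing_correct=(not treated)
                    or not rng.random() < config.p_incorrect_dosing,
                    tumor_2hg=float(value),
                    cellularity=float(np.clip(rng.beta(8, 3), 1e-3, 1.0)),
                    c_5hmc=bio["hmc5_pct"] * 10.0,  # counts with C denominator 1000
                    c_5mc=float(max(rng.normal(45.0, 5.0), 0.0)),
                    c_c=1000.0,
                    ki67_pct=bio["ki67_pct"],
                    cd3_density=bio["cd3_density"],
                    cd8_density=bio["cd8_density"],
                    **series,
                )
            )
    return subjects, externals


def simulate_biomarkers(
    log10_2hg: float,
    config: GeneratorConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Biomarker values linearly coupled to log10 2-HG, truncated at zero.

    Ki-67 couples positively (more 2-HG, more proliferation); 5hmC% couples
    negatively (2-HG inhibits TET hydroxylases); immune densities follow their
    configured slopes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for name, cpl in config.coupling.items():
        value = cpl.intercept + cpl.slope * log10_2hg + cpl.noise_sd * rng.standard_normal()
        out[name] = float(max(value, 0.0))
    return out


def simulate_expression(
    config: GeneratorConfig,
    covariate: Sequence[float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Gene × sample expression matrix with a planted 2-HG signature.

    Returns ``(matrix, gene_ids, signature_gene_ids)``.  Background genes are
    independent of the covariate; signature genes are linear in the z-scored
    covariate (population z-scoring) on the log2 scale.  The returned matrix is
    strictly positive (log2 values exponentiated).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = config.expression
    x = np.asarray(covariate, dtype=float)
    z = (x - x.mean()) / x.std()  # population denominator
    n_samples = x.size
    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    log2_expr = baselines[:, None] + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, n_samples)
    )
    # alternate signature signs so the planted set has both directions
    signs = np.where(np.arange(spec.n_signature_genes) % 2 == 0, 1.0, -1.0)
    log2_expr[: spec.n_signature_genes] += spec.effect * signs[:, None] * z[None, :]
    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    signature = gene_ids[: spec.n_signature_genes]
    return 2.0**log2_expr, gene_ids, signature


def simulate_spd_series(
    config: GeneratorConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """One subject's postoperative lesion series.

    Baseline SPD is lognormal; visit v has SPD = baseline · (1 + drift)^v ·
    exp(noise).  With probability ``no_residual_fraction`` the resection is
    complete: no measurable baseline and an all-zero series.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = config.spd
    days = tuple(
        spec.visit_interval_days * (v + 1) for v in range(spec.n_visits)
    )
    if rng.random() < spec.no_residual_fraction:
        return {
            "baseline_spd": None,
            "no_residual_disease": True,
            "lesion_days": days,
            "lesion_spd": (0.0,) * spec.n_visits,
        }
    params = moment_match_lognormal(spec.baseline_mean, spec.baseline_sd)
    baseline = float(10.0 ** (params.location + params.scale * rng.standard_normal()))
    factor = 1.0 + spec.drift_per_visit
    spd = tuple(
        float(baseline * factor ** (v + 1)
              * math.exp(spec.noise_sd * rng.standard_normal()))
        for v in range(spec.n_visits)
    )
    return {
        "baseline_spd": baseline,
        "no_residual_disease": False,
        "lesion_days": days,
        "lesion_spd": spd,
    }


# ---------------------------------------------------------------------------
# Matrix / gene-set text formats

def write_expression_matrix(matrix: np.ndarray, gene_ids, sample_ids, path) -> None:
    """Tab-separated genes × samples with a header row of sample ids."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for gid, row in zip(gene_ids, matrix):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        gene_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows, dtype=float), gene_ids, sample_ids


def write_gmt(sets: dict[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
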