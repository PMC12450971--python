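"""Synthetic cohort generator.

Emulates the statistical structure of a paired pre/post-treatment PET/CT
radiomics study: 107 radiomic features per image series across four series,
15 mixed-type clinical variables, and a binary local-recurrence outcome with
roughly 22.9% prevalence. Radiomic features come in correlated blocks (a
shared latent factor per block) so that redundancy filters have something to
do; a sparse subset of features carries true signal through a logistic
outcome model whose intercept is calibrated by root-finding so the marginal
event probability matches the requested prevalence.

All randomness flows from the single integer seed in :class:`GeneratorSpec`
through one named :class:`numpy.random.Generator`; there is no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import CohortSpecError
from .table import CLINICAL_GROUP, GROUP_SEP, RADIOMIC_GROUPS, FeatureTable

# Clinical column blueprint: (name, kind, params). Kinds: "ordinal" (uniform
# integer levels), "binary" (Bernoulli), "normal" (Gaussian). p16 status is a
# binary with a paired missing-indicator column, mirroring cohorts where HPV
# surrogate testing is incomplete.
CLINICAL_BLUEPRINT: tuple[tuple[str, str, tuple], ...] = (
    ("t_stage", "ordinal", (1, 4)),
    ("smoking", "binary", (0.5,)),
    ("p16_positive", "binary_with_missing", (0.7, 0.25)),
    ("p16_missing", "indicator", ()),  # filled alongside p16_positive
    ("rt_dose_gy", "normal", (70.0, 4.0)),
    ("rt_fractions", "normal", (33.0, 3.0)),
    ("age_years", "normal", (60.0, 10.0)),
    ("sex_male", "binary", (0.8,)),
    ("chemotherapy", "binary", (0.6,)),
    ("alcohol_use", "binary", (0.4,)),
    ("diabetes", "binary", (0.2,)),
    ("bmi", "normal", (26.0, 4.0)),
    ("hemoglobin", "normal", (13.5, 1.5)),
    ("weight_loss_pct", "normal", (5.0, 3.0)),
    ("followup_weeks", "normal", (14.0, 2.0)),
)

#: Clinical variables that carry outcome signal by default, with standardized
#: log-odds coefficients. Higher T stage and smoking raise risk; p16
#: positivity and delivered treatment intensity lower it.
DEFAULT_CLINICAL_EFFECTS: dict[str, float] = {
    "t_stage": 0.5,
    "smoking": 0.4,
    "p16_positive": -0.5,
    "rt_dose_gy": -0.3,
    "rt_fractions": -0.3,
}

DEFAULT_RADIOMIC_EFFECT = 0.45


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` maps full column names to standardized log-odds
    coefficients; when None, a default sparse effect vector is built from
    ``n_informative_radiomic`` block-leader features (0.45 each, spread
    round-robin across the four series in distinct correlation blocks) and
    ``n_informative_clinical`` named clinical variables.
    """

    n_samples: int = 249
    n_radiomic_per_series: int = 107
    series_names: tuple[str, ...] = RADIOMIC_GROUPS
    n_clinical: int = 15
    target_prevalence: float = 0.229
    block_size: int = 5
    within_block_correlation: float = 0.8
    n_informative_radiomic: int = 8
    n_informative_clinical: int = 5
    effect_sizes: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise CohortSpecError("n_samples must be positive (empty cohort requested)")
        if not 0.0 < self.target_prevalence < 1.0:
            raise CohortSpecError(
                f"target_prevalence must lie strictly in (0,1), got {self.target_prevalence}"
            )
        if len(self.series_names) != 4:
            raise CohortSpecError("exactly four radiomic series are expected")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise CohortSpecError("within_block_correlation must lie in [0,1)")
        if self.n_informative_radiomic > self.n_radiomic_per_series * 4:
            raise CohortSpecError("more informative radiomic features than columns")
        if self.n_clinical > len(CLINICAL_BLUEPRINT):
            raise CohortSpecError(
                f"n_clinical at most {len(CLINICAL_BLUEPRINT)} named columns"
            )
        if self.block_size < 1:
            raise CohortSpecError("block_size must be >= 1")

    # -- naming -------------------------------------------------------------
    @property
    def radiomic_names(self) -> list[str]:
        return [
            f"{series}{GROUP_SEP}radiomic_{i:03d}"
            for series in self.series_names
            for i in range(self.n_radiomic_per_series)
        ]

    @property
    def clinical_names(self) -> list[str]:
        return [
            f"{CLINICAL_GROUP}{GROUP_SEP}{name}"
            for name, _, _ in CLINICAL_BLUEPRINT[: self.n_clinical]
        ]

    @property
    def n_features(self) -> int:
        return self.n_radiomic_per_series * 4 + self.n_clinical

    def default_informative_radiomic(self) -> list[str]:
        """Block-leader features, round-robin over series, distinct blocks."""
        names = []
        for i in range(self.n_informative_radiomic):
            series = self.series_names[i % 4]
            idx = (i // 4) * self.block_size
            if idx >= self.n_radiomic_per_series:
                raise CohortSpecError("not enough blocks to place informative features")
            names.append(f"{series}{GROUP_SEP}radiomic_{idx:03d}")
        return names

    def effect_vector(self) -> dict[str, float]:
        """Full-name -> standardized log-odds coefficient (non-zero entries)."""
        if self.effect_sizes is not None:
            return dict(self.effect_sizes)
        effects = {n: DEFAULT_RADIOMIC_EFFECT for n in self.default_informative_radiomic()}
        clin = list(DEFAULT_CLINICAL_EFFECTS.items())[: self.n_informative_clinical]
        for name, beta in clin:
            effects[f"{CLINICAL_GROUP}{GROUP_SEP}{name}"] = beta
        return effects

    def to_json(self) -> str:
        d = asdict(self)
        d["series_names"] = list(d["series_names"])
        d["effect_vector"] = self.effect_vector()
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# column-wise moments for standardization inside the logit


def _clinical_moments(name: str, kind: str, params: tuple) -> tuple[float, float]:
    if kind == "ordinal":
        lo, hi = params
        levels = np.arange(lo, hi + 1)
        return float(levels.mean()), float(levels.std())
    if kind == "binary":
        (p,) = params
        return p, math.sqrt(p * (1 - p))
    if kind == "binary_with_missing":
        p_pos, p_miss = params
        p = p_pos * (1 - p_miss)  # observed positives; missing coded 0
        return p, math.sqrt(p * (1 - p))
    if kind == "indicator":
        # p16_missing shares p_miss with its parent column
        p = CLINICAL_BLUEPRINT[2][2][1]
        return p, math.sqrt(p * (1 - p))
    if kind == "normal":
        mu, sd = params
        return mu, sd
    raise ValueError(f"unknown clinical kind {kind!r}")


def _generate_arrays(spec: GeneratorSpec, rng: np.random.Generator):
    """Draw the feature matrix and the standardized linear predictor.

    Returns (values ndarray, column names, eta, intercept, labels).
    """
    n = spec.n_samples
    rho = spec.within_block_correlation

    # Radiomic blocks: x = sqrt(rho) * f_block + sqrt(1-rho) * eps, unit variance.
    per_series = spec.n_radiomic_per_series
    n_rad = per_series * 4
    rad = np.empty((n, n_rad))
    n_blocks = math.ceil(per_series / spec.block_size)
    for s in range(4):
        factors = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, per_series))
        for j in range(per_series):
            b = j // spec.block_size
            rad[:, s * per_series + j] = (
                math.sqrt(rho) * factors[:, b] + math.sqrt(1 - rho) * eps[:, j]
            )

    # Clinical columns per blueprint.
    clin_cols = CLINICAL_BLUEPRINT[: spec.n_clinical]
    clin = np.empty((n, len(clin_cols)))
    p16_missing = None
    for j, (name, kind, params) in enumerate(clin_cols):
        if kind == "ordinal":
            lo, hi = params
            clin[:, j] = rng.integers(lo, hi + 1, size=n)
        elif kind == "binary":
            (p,) = params
            clin[:, j] = (rng.random(n) < p).astype(float)
        elif kind == "binary_with_missing":
            p_pos, p_miss = params
            p16_missing = (rng.random(n) < p_miss).astype(float)
            known = (rng.random(n) < p_pos).astype(float)
            clin[:, j] = known * (1 - p16_missing)
        elif kind == "indicator":
            clin[:, j] = p16_missing
        elif kind == "normal":
            mu, sd = params
            clin[:, j] = mu + sd * rng.standard_normal(n)

    columns = spec.radiomic_names + spec.clinical_names
    values = np.hstack([rad, clin])

    # Standardized linear predictor over the informative columns.
    effects = spec.effect_vector()
    col_index = {c: i for i, c in enumerate(columns)}
    eta = np.zeros(n)
    for name, beta in effects.items():
        if beta == 0:
            continue
        if name not in col_index:
            raise CohortSpecError(f"effect on unknown column {name!r}")
        j = col_index[name]
        if name.startswith(CLINICAL_GROUP + GROUP_SEP):
            short = name.split(GROUP_SEP, 1)[1]
            blue = next(b for b in CLINICAL_BLUEPRINT if b[0] == short)
            mu, sd = _clinical_moments(*blue)
        else:
            mu, sd = 0.0, 1.0  # radiomic features are marginally standard normal
        eta += beta * (values[:, j] - mu) / sd

    intercept = _calibrate_intercept(eta, spec.target_prevalence)
    labels = (rng.random(n) < expit(intercept + eta)).astype(int)
    return values, columns, eta, intercept, labels


def _calibrate_intercept(eta: np.ndarray, prevalence: float, tol: float = 1e-6) -> float:
    """Root-find b0 so the mean event probability over eta equals prevalence."""

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - prevalence)

    lo, hi = -30.0, 30.0
    return float(brentq(gap, lo, hi, xtol=tol))


def generate_cohort(spec: GeneratorSpec) -> FeatureTable:
    """Draw one cohort; bit-identical for identical specs (same seed)."""
    rng = np.random.default_rng(spec.seed)
    values, columns, eta, intercept, labels = _generate_arrays(spec, rng)
    ids = pd.Index([f"S{i:06d}" for i in range(spec.n_samples)], name="sample_id")
    frame = pd.DataFrame(values, index=ids, columns=columns)
    meta = {
        "generator": "recuq.synthetic",
        "seed": spec.seed,
        "intercept": intercept,
        "effect_vector": spec.effect_vector(),
    }
    return FeatureTable(frame, pd.Series(labels, index=ids, name="label"), meta)


def true_posterior(spec: GeneratorSpec, table: FeatureTable) -> np.ndarray:
    """Exact event probability of each sample under the generating model.

    Recomputes the standardized linear predictor from the realized feature
    values and the spec's effect vector, adding the calibrated intercept
    stored in the table's metadata. This is the perfectly calibrated
    probability model for cohorts drawn from ``spec``.
    """
    effects = spec.effect_vector()
    eta = np.zeros(table.n_samples)
    for name, beta in effects.items():
        if beta == 0:
            continue
        if name.startswith(CLINICAL_GROUP + GROUP_SEP):
            short = name.split(GROUP_SEP, 1)[1]
            blue = next(b for b in CLINICAL_BLUEPRINT if b[0] == short)
            mu, sd = _clinical_moments(*blue)
        else:
            mu, sd = 0.0, 1.0
        eta += beta * (table.values[name].to_numpy(float) - mu) / sd
    return expit(table.meta["intercept"] + eta)


def write_cohort(table: FeatureTable, csv_path, spec: GeneratorSpec) -> None:
    """Cohort CSV plus a sidecar JSON with the spec and true effect vector."""
    table.to_csv(csv_path)
    sidecar = str(csv_path) + ".json"
    with open(sidecar, "w") as fh:
        fh.write(spec.to_json())


def oracle_bayes_auc(spec: GeneratorSpec, n_mc: int = 100_000) -> float:
    """Monte-Carlo AUC of the true generating logit against simulated labels.

    This is the Bayes-optimal discrimination of the generating model and an
    upper bound (up to Monte-Carlo error) for anything fitted on cohorts
    drawn from ``spec``.
    """
    from sklearn.metrics import roc_auc_score

    if n_mc < 1:
        raise CohortSpecError("n_mc must be positive")
    mc_spec = GeneratorSpec(**{**asdict(spec), "n_samples": n_mc})
    rng = np.random.default_rng(mc_spec.seed)
    _, _, eta, _, labels = _generate_arrays(mc_spec, rng)
    if labels.min() == labels.max():
        return 0.5
    if np.allclose(eta, eta[0]):
        return 0.5  # no signal: logit is constant, AUC is chance by convention
    return float(roc_auc_score(labels, eta))
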