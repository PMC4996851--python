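"""Synthetic cohort generation.

Emulates the covariate structure of a secondary-prevention coronary artery
disease cohort: a clinical block (age, gender, BMI, LDL/HDL cholesterol
ratio, current smoking, diabetes, hypertension, C-reactive protein,
creatinine) and, for the genetic scenario, 55 additive allele-dosage
variants (51 SNPs and 4 indels).  Only a few summary anchors of the source
population are public (median age about 63 years, 77.6% male), so the
remaining distribution parameters are plausible defaults and every one of
them can be overridden through :class:`CovariateSpec`.

Correlation among the clinical columns is induced with a Gaussian copula on
a target rank-correlation matrix; dosage columns are drawn independently as
the sum of two Bernoulli allele draws (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CovariateSpec",
    "CovariateMatrix",
    "default_scenario_spec",
    "generate_cohort",
    "make_true_coefficients",
]

KINDS = ("continuous", "binary", "dosage")

#: fixed stream for the default variant allele frequencies, so that
#: ``default_scenario_spec(2)`` is the same object on every call
_VARIANT_FREQ_SEED = 55_2016


@dataclass(frozen=True)
class Column:
    name: str
    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 < self.params["prob"] < 1.0:
            raise ValueError(f"{self.name}: success probability must be in (0,1)")
        if self.kind == "dosage" and not 0.0 < self.params["freq"] < 1.0:
            raise ValueError(f"{self.name}: allele frequency must be in (0,1)")
        if self.kind == "continuous":
            dist = self.params.get("dist", "normal")
            if dist not in ("normal", "lognormal"):
                raise ValueError(f"{self.name}: unknown distribution {dist!r}")

    @property
    def sd(self) -> float:
        """Marginal standard deviation implied by the parameters."""
        if self.kind == "continuous":
            if self.params.get("dist", "normal") == "normal":
                return float(self.params["sd"])
            s2 = self.params["logsd"] ** 2
            return float(
                np.exp(self.params["logmean"] + s2 / 2.0) * np.sqrt(np.expm1(s2))
            )
        if self.kind == "binary":
            p = self.params["prob"]
            return float(np.sqrt(p * (1.0 - p)))
        f = self.params["freq"]
        return float(np.sqrt(2.0 * f * (1.0 - f)))

    @property
    def mean(self) -> float:
        if self.kind == "continuous":
            if self.params.get("dist", "normal") == "normal":
                return float(self.params["mean"])
            return float(
                np.exp(self.params["logmean"] + self.params["logsd"] ** 2 / 2.0)
            )
        if self.kind == "binary":
            return float(self.params["prob"])
        return float(2.0 * self.params["freq"])


@dataclass
class CovariateSpec:
    """Declarative description of a cohort's predictor columns.

    Parameters
    ----------
    columns
        Ordered list of :class:`Column` (or ``(name, kind, params)`` tuples).
    correlation
        Optional target rank-correlation matrix for the non-dosage block
        (symmetric, unit diagonal, positive semi-definite).  Dosage columns
        are always independent.
    """

    columns: list = field(default_factory=list)
    correlation: np.ndarray | None = None

    def __post_init__(self):
        self.columns = [
            c if isinstance(c, Column) else Column(*c) for c in self.columns
        ]
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self.clinical_indices)
            if R.shape != (k, k):
                raise ValueError(
                    f"correlation matrix must be {k}x{k} (non-dosage block)"
                )
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            self.correlation = R

    @property
    def p(self) -> int:
        return len(self.columns)

    @property
    def names(self) -> list:
        return [c.name for c in self.columns]

    @property
    def clinical_indices(self) -> list:
        return [i for i, c in enumerate(self.columns) if c.kind != "dosage"]

    @property
    def dosage_indices(self) -> list:
        return [i for i, c in enumerate(self.columns) if c.kind == "dosage"]

    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.columns])

    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.columns])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "columns": [
                {"name": c.name, "kind": c.kind, "params": dict(c.params)}
                for c in self.columns
            ]
        }
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        cols = [Column(c["name"], c["kind"], c["params"]) for c in d["columns"]]
        corr = d.get("correlation")
        return cls(cols, None if corr is None else np.asarray(corr, float))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CovariateSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class CovariateMatrix:
    """An n x p predictor table tied to the spec that generated it."""

    values: np.ndarray
    spec: CovariateSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError("need n >= 2 individuals and p >= 1 predictors")
        if p != self.spec.p:
            raise ValueError("value columns do not match spec")
        if not np.isfinite(self.values).all():
            raise ValueError("covariates must be finite (no missing values)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list:
        return self.spec.names

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.names)


_CLINICAL = [
    ("age", "continuous", {"dist": "normal", "mean": 63.0, "sd": 10.0}),
    ("male", "binary", {"prob": 0.776}),
    ("bmi", "continuous", {"dist": "normal", "mean": 27.0, "sd": 4.0}),
    # median ~2.5, right-skewed
    ("ldl_hdl_ratio", "continuous", {"dist": "lognormal", "logmean": float(np.log(2.5)), "logsd": 0.35}),
    ("current_smoking", "binary", {"prob": 0.2}),
    ("diabetes", "binary", {"prob": 0.25}),
    ("hypertension", "binary", {"prob": 0.8}),
    ("crp", "continuous", {"dist": "lognormal", "logmean": float(np.log(2.0)), "logsd": 1.0}),
    ("creatinine", "continuous", {"dist": "lognormal", "logmean": 0.0, "logsd": 0.2}),
]

# mild, plausible co-morbidity structure for the clinical block (rank scale)
_CLINICAL_RANK_CORR = {
    ("age", "hypertension"): 0.20,
    ("bmi", "diabetes"): 0.25,
    ("bmi", "crp"): 0.15,
    ("age", "current_smoking"): -0.10,
    ("age", "creatinine"): 0.15,
}


def _default_correlation() -> np.ndarray:
    names = [c[0] for c in _CLINICAL]
    k = len(names)
    R = np.eye(k)
    for (a, b), r in _CLINICAL_RANK_CORR.items():
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = r
    return R


def default_scenario_spec(scenario: int) -> CovariateSpec:
    """Built-in predictor sets.

    Scenario 1: the 9 clinical/biomarker columns.  Scenario 2: those plus 55
    allele-dosage variants (51 SNPs, 4 indels) with allele frequencies drawn
    once, reproducibly, from Uniform(0.05, 0.5).
    """
    if scenario not in (1, 2):
        raise ValueError(f"unknown scenario {scenario!r}; expected 1 or 2")
    cols = [Column(*c) for c in _CLINICAL]
    if scenario == 2:
        rng = np.random.default_rng(_VARIANT_FREQ_SEED)
        freqs = rng.uniform(0.05, 0.5, size=55)
        for i in range(51):
            cols.append(Column(f"snp_{i + 1:02d}", "dosage", {"freq": float(freqs[i])}))
        for i in range(4):
            cols.append(
                Column(f"indel_{i + 1}", "dosage", {"freq": float(freqs[51 + i])})
            )
    return CovariateSpec(cols, _default_correlation())


def generate_cohort(spec: CovariateSpec, n: int, seed: int) -> CovariateMatrix:
    """Draw an n-individual cohort from ``spec``; deterministic given the seed.

    The non-dosage block is generated through a Gaussian copula: latent
    normals with Pearson correlation ``2 sin(pi * rho_s / 6)`` (the exact
    normal-score transform of a target Spearman rho) are pushed through each
    column's marginal.  Dosages are sums of two independent Bernoulli(freq)
    allele draws.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    X = np.empty((n, spec.p))

    clin = spec.clinical_indices
    if clin:
        k = len(clin)
        if spec.correlation is not None:
            Rz = 2.0 * np.sin(np.pi * spec.correlation / 6.0)
            np.fill_diagonal(Rz, 1.0)
            # guard: the sin transform can nudge eigenvalues slightly negative
            w, V = np.linalg.eigh(Rz)
            L = V * np.sqrt(np.clip(w, 0.0, None))
            Z = rng.standard_normal((n, k)) @ L.T
        else:
            Z = rng.standard_normal((n, k))
        from scipy.stats import norm

        for pos, j in enumerate(clin):
            col = spec.columns[j]
            z = Z[:, pos]
            if col.kind == "continuous":
                if col.params.get("dist", "normal") == "normal":
                    X[:, j] = col.params["mean"] + col.params["sd"] * z
                else:
                    X[:, j] = np.exp(col.params["logmean"] + col.params["logsd"] * z)
            else:
                # binary via the copula quantile: indicator increasing in z
                # so positive latent correlation stays positive
                X[:, j] = (norm.cdf(z) > 1.0 - col.params["prob"]).astype(float)

    for j in spec.dosage_indices:
        f = spec.columns[j].params["freq"]
        X[:, j] = (rng.random((n, 2)) < f).sum(axis=1).astype(float)

    return CovariateMatrix(X, spec)


def make_true_coefficients(
    spec: CovariateSpec, effect_scale: float, seed: int
) -> np.ndarray:
    """Random true log-hazard-ratio vector with comparable prognostic strength.

    Coefficients are drawn N(0, effect_scale^2) on the standardized scale,
    clipped to +/- 3*effect_scale, then divided by each column's marginal
    standard deviation so a one-SD change in any predictor moves the linear
    predictor by a comparable amount.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    rng = np.random.default_rng(seed)
    b_std = rng.normal(0.0, effect_scale, size=spec.p) if effect_scale > 0 else np.zeros(spec.p)
    b_std = np.clip(b_std, -3.0 * effect_scale, 3.0 * effect_scale)
    return b_std / spec.sds()
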