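"""Synthetic IVF cohort generator with a known ground-truth implantation model.

Emulates the statistical structure a per-transfer IVF cohort exhibits:

* feature marginals (truncated normals for continuous features, Bernoulli /
  categorical for coded features) set to the training-cohort baseline values;
* a per-embryo implantation probability that is a known, partly nonlinear
  function of patient and embryo features; and
* a shared-patient latent "receptivity" term on the log-odds scale that makes
  the two embryos of a double transfer positively dependent — the outcome of a
  DET is deliberately *not* binomial in the two marginal probabilities.

Because the truth model is known, every downstream stage (training, selection,
calibration, algorithm comparison) can be validated against exact or
Monte-Carlo oracles without any patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .cohort_io import (
    EMBRYO_FEATURES,
    PATIENT_FEATURES,
    SELECTED_FEATURES,
    EmbryoRecord,
    PatientRecord,
    TransferRecord,
)
from .errors import ConfigurationError

__all__ = [
    "ContinuousMarginal",
    "BinaryMarginal",
    "CategoricalMarginal",
    "NonlinearTerm",
    "TruthModel",
    "GeneratorConfig",
    "DEFAULT_MARGINALS",
    "DEFAULT_DET_FRACTION",
    "default_truth_model",
    "default_config",
    "generate_cohort",
    "marginal_probability",
    "joint_det_probabilities",
    "load_generator_config",
    "save_generator_config",
]

# Training-cohort composition: 564 double transfers among 5828 patients.
DEFAULT_DET_FRACTION = 564 / 5828

_QUAD_NODES = 64  # Gauss–Hermite nodes for latent-variable quadrature


@dataclass(frozen=True)
class ContinuousMarginal:
    """Truncated-normal marginal; optionally rounded to integers (counts)."""

    mean: float
    sd: float
    lower: float
    upper: float
    integer: bool = False
    kind: str = "continuous"

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"feature_marginals[{name}].sd: SD must be >= 0")
        if self.lower > self.upper:
            raise ConfigurationError(f"feature_marginals[{name}]: lower > upper")

    def _dist(self):
        if self.sd == 0:
            return None
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            x = np.full(n, self.mean)
        else:
            dist = self._dist()
            x = dist.ppf(rng.random(n))
        return np.round(x) if self.integer else x

    def exact_mean(self) -> float:
        """Mean of the generating distribution (after truncation and rounding)."""
        if self.sd == 0:
            return round(self.mean) if self.integer else self.mean
        dist = self._dist()
        if not self.integer:
            return float(dist.mean())
        ks, probs = self._pmf()
        return float(np.sum(ks * probs))

    def _pmf(self) -> tuple[np.ndarray, np.ndarray]:
        dist = self._dist()
        ks = np.arange(math.floor(self.lower), math.ceil(self.upper) + 1)
        probs = dist.cdf(ks + 0.5) - dist.cdf(ks - 0.5)
        return ks, probs / np.sum(probs)

    def prob_condition(self, op: str, value: float) -> float:
        """P(X op value) under the generating distribution."""
        if self.sd == 0:
            x = round(self.mean) if self.integer else self.mean
            return float(_OPS[op](x, value))
        if self.integer:
            ks, probs = self._pmf()
            return float(np.sum(probs[_OPS[op](ks, value)]))
        dist = self._dist()
        if op == "gt" or op == "ge":  # continuous: P(X > v) = P(X >= v)
            return float(dist.sf(value))
        return float(dist.cdf(value))


@dataclass(frozen=True)
class BinaryMarginal:
    """Bernoulli marginal (0/1 indicator)."""

    p: float
    kind: str = "binary"

    def validate(self, name: str) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"feature_marginals[{name}].p: must be in [0,1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)

    def exact_mean(self) -> float:
        return self.p

    def prob_condition(self, op: str, value: float) -> float:
        return float(_OPS[op](0.0, value)) * (1 - self.p) + float(_OPS[op](1.0, value)) * self.p


@dataclass(frozen=True)
class CategoricalMarginal:
    """Ordinal code 0..k-1 drawn at the configured level probabilities."""

    probs: tuple[float, ...]
    kind: str = "categorical"

    def validate(self, name: str) -> None:
        if any(p < 0 for p in self.probs) or not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"feature_marginals[{name}].probs: must be non-negative and sum to 1"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(len(self.probs), size=n, p=np.asarray(self.probs)).astype(float)

    def exact_mean(self) -> float:
        return float(sum(i * p for i, p in enumerate(self.probs)))

    def prob_condition(self, op: str, value: float) -> float:
        return float(sum(p for i, p in enumerate(self.probs) if _OPS[op](float(i), value)))


Marginal = ContinuousMarginal | BinaryMarginal | CategoricalMarginal


def _cont(mean: float, sd: float, integer: bool = False, floor_zero: bool = True) -> ContinuousMarginal:
    """Truncation at mean ± 4 SD, floored at 0 for counts and hormone levels."""
    lower = mean - 4 * sd
    if floor_zero:
        lower = max(0.0, lower)
    return ContinuousMarginal(mean=mean, sd=sd, lower=lower, upper=mean + 4 * sd, integer=integer)


# Training-cohort baseline marginals for the 19 selected features.
# Fragment is coded ordinal {0,1,2} (none / 5–15% / >15%) and equality ordinal
# {0..4} (equal … very unequal); their level probabilities reproduce the
# reported means (0.37 and 0.91).
DEFAULT_MARGINALS: dict[str, Marginal] = {
    "age": _cont(30.46, 4.20, floor_zero=False),
    "attempt_times_ivf": _cont(0.95, 0.43, integer=True),  # prior attempts, 0-based
    "antral_follicle_count": _cont(13.64, 6.13),
    "fsh": _cont(7.59, 2.35),
    "lh": _cont(4.71, 3.26),
    "e2_hcg_day": _cont(2810.88, 1424.43),
    "endometrial_thickness": _cont(11.79, 2.40, floor_zero=False),
    "mii": _cont(9.86, 4.14, integer=True),
    "two_pn": _cont(6.79, 3.35, integer=True),
    "oocyte_number": _cont(11.03, 4.45, integer=True),
    "two_pn_mii_ratio": ContinuousMarginal(mean=0.70, sd=0.19, lower=0.0, upper=1.0),
    "agonist_protocol": BinaryMarginal(0.714),
    "endometrial_type_a": BinaryMarginal(0.833),
    "endometrial_type_c": BinaryMarginal(0.214),
    "secondary_infertility": BinaryMarginal(0.351),
    "icsi": BinaryMarginal(0.245),
    "blastomere_number": _cont(7.93, 0.89, integer=True),
    "fragment": CategoricalMarginal((0.66, 0.31, 0.03)),  # mean 0.37
    "equality": CategoricalMarginal((0.44, 0.32, 0.15, 0.07, 0.02)),  # mean 0.91
}

_OPS = {
    "gt": np.greater,
    "ge": np.greater_equal,
    "lt": np.less,
    "le": np.less_equal,
}


@dataclass(frozen=True)
class NonlinearTerm:
    """Log-odds offset applied where a conjunction of feature conditions holds."""

    conditions: tuple[tuple[str, Literal["gt", "ge", "lt", "le"], float], ...]
    offset: float

    def indicator(self, table: pd.DataFrame) -> np.ndarray:
        ind = np.ones(len(table), dtype=bool)
        for feature, op, value in self.conditions:
            ind &= _OPS[op](table[feature].to_numpy(dtype=float), value)
        return ind

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(f for f, _, _ in self.conditions)


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth per-embryo implantation model on the log-odds scale.

    Conditional on the patient's latent receptivity u ~ Normal(0, latent_sd²),
    each transferred embryo implants independently with probability
    sigmoid(intercept + Σ coef·x + Σ offset·1[predicate] + u); the marginal
    probability integrates u out by Gauss–Hermite quadrature.
    """

    intercept: float
    coefficients: dict[str, float]
    nonlinear_terms: tuple[NonlinearTerm, ...] = ()
    latent_sd: float = 1.0

    def validate(self) -> None:
        if self.latent_sd < 0:
            raise ConfigurationError("truth.latent_sd: must be >= 0")

    @property
    def required_features(self) -> tuple[str, ...]:
        names = list(self.coefficients)
        for term in self.nonlinear_terms:
            for f in term.features:
                if f not in names:
                    names.append(f)
        return tuple(names)

    def log_odds(self, table: pd.DataFrame) -> np.ndarray:
        """Deterministic log-odds (latent term excluded) for each row."""
        used = table[list(self.required_features)]
        if used.isna().to_numpy().any():
            bad = used.columns[used.isna().any()].tolist()
            raise ValueError(f"truth model requires non-missing features: {bad}")
        eta = np.full(len(table), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            eta += coef * table[name].to_numpy(dtype=float)
        for term in self.nonlinear_terms:
            eta += term.offset * term.indicator(table)
        return eta


def default_truth_model(latent_sd: float = 1.0, target_marginal: float = 0.33) -> TruthModel:
    """Default truth: linear effects plus clinically motivated threshold,
    window and interaction terms, so the true log-odds is decidedly not
    linear in the features.

    Ovarian-reserve markers (FSH, LH, AFC) and endometrial thickness act
    through thresholds/windows rather than linear slopes: an FSH above the
    classic 10 IU/L reserve cutoff, a mid-range LH window, a low-AFC cliff,
    an endometrial receptive window (10–14 mm), a steep decline beyond age
    35, and a good-fertilization × on-time-cleavage embryo interaction.
    This mirrors the divergence the pipeline is built to expose: such
    features carry little marginal (regression-visible) signal yet strong
    predictive (tree-visible) signal.

    The intercept is calibrated so the log-odds at the marginal feature means
    equals ``logit(target_marginal)``.
    """
    coefficients = {
        "age": -0.05,
        "attempt_times_ivf": -0.35,
        "antral_follicle_count": 0.0,
        "fsh": 0.0,
        "lh": 0.0,
        "e2_hcg_day": 0.00012,
        "endometrial_thickness": 0.0,
        "mii": 0.02,
        "two_pn": 0.03,
        "oocyte_number": 0.01,
        "two_pn_mii_ratio": 0.5,
        "agonist_protocol": 0.15,
        "endometrial_type_a": 0.20,
        "endometrial_type_c": -0.15,
        "secondary_infertility": -0.10,
        "icsi": 0.0,
        "blastomere_number": 0.25,
        "fragment": -0.35,
        "equality": -0.20,
    }
    nonlinear = (
        # receptive endometrial window: implantation favours 10–14 mm lining
        NonlinearTerm(
            conditions=(
                ("endometrial_thickness", "ge", 10.0),
                ("endometrial_thickness", "le", 14.0),
            ),
            offset=1.2,
        ),
        # steep decline in implantation beyond age 35
        NonlinearTerm(conditions=(("age", "gt", 35.0),), offset=-1.4),
        # good fertilization rate and on-time cleavage synergize
        NonlinearTerm(
            conditions=(("two_pn_mii_ratio", "gt", 0.8), ("blastomere_number", "ge", 8.0)),
            offset=0.9,
        ),
        # diminished ovarian reserve: FSH above the classic 10 IU/L cutoff
        NonlinearTerm(conditions=(("fsh", "gt", 10.0),), offset=-1.0),
        # mid-range LH window is favourable; suppressed or high LH is not
        NonlinearTerm(conditions=(("lh", "ge", 2.0), ("lh", "le", 8.0)), offset=0.9),
        # low antral follicle count cliff
        NonlinearTerm(conditions=(("antral_follicle_count", "lt", 7.0),), offset=-0.8),
    )
    # calibrate the intercept so the expected log-odds (linear means plus the
    # nonlinear terms' expected contribution under independent marginals)
    # equals logit(target_marginal)
    mean_eta = sum(
        coef * DEFAULT_MARGINALS[name].exact_mean() for name, coef in coefficients.items()
    )
    for term in nonlinear:
        prob = 1.0
        for feature, op, value in term.conditions:
            prob *= DEFAULT_MARGINALS[feature].prob_condition(op, value)
        mean_eta += term.offset * prob
    intercept = float(logit(target_marginal)) - mean_eta
    return TruthModel(
        intercept=intercept,
        coefficients=coefficients,
        nonlinear_terms=nonlinear,
        latent_sd=latent_sd,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort; reproducible from ``seed``.

    ``identical_det_embryos`` is a diagnostic switch that copies embryo 1's
    morphology onto embryo 2 of every DET, so empirical twin rates can be
    compared against closed-form formulas for exchangeable pairs.
    """

    n_patients: int
    det_fraction: float = DEFAULT_DET_FRACTION
    feature_marginals: dict[str, Marginal] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    truth: TruthModel = field(default_factory=default_truth_model)
    missing_rate: float = 0.05
    seed: int = 0
    identical_det_embryos: bool = False

    @property
    def latent_sd(self) -> float:
        return self.truth.latent_sd

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients: must be >= 0")
        if not 0.0 <= self.det_fraction <= 1.0:
            raise ConfigurationError("det_fraction: must be in [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate: must be in [0,1]")
        self.truth.validate()
        missing = [f for f in SELECTED_FEATURES if f not in self.feature_marginals]
        if missing:
            raise ConfigurationError(f"feature_marginals: missing feature(s) {missing}")
        for name, marginal in self.feature_marginals.items():
            marginal.validate(name)


def default_config(n_patients: int, seed: int = 0, latent_sd: float = 1.0, **kwargs) -> GeneratorConfig:
    """Convenience constructor with the default marginals and truth model."""
    return GeneratorConfig(
        n_patients=n_patients,
        truth=default_truth_model(latent_sd=latent_sd),
        seed=seed,
        **kwargs,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def generate_cohort(config: GeneratorConfig) -> list[TransferRecord]:
    """Draw a synthetic cohort of transfer records.

    For each patient: features from the configured marginals, transfer type
    Bernoulli(det_fraction), one latent receptivity u ~ Normal(0, latent_sd²),
    and each transferred embryo implanting independently *given u* with
    probability sigmoid(truth log-odds + u).  Missing values are then injected
    completely at random at ``missing_rate`` per feature cell; outcome and
    transfer-type columns are never missing.  Fully reproducible from ``seed``.
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    patient = pd.DataFrame(
        {name: config.feature_marginals[name].sample(rng, n) for name in PATIENT_FEATURES}
    )
    is_det = rng.random(n) < config.det_fraction

    embryo1 = pd.DataFrame(
        {name: config.feature_marginals[name].sample(rng, n) for name in EMBRYO_FEATURES}
    )
    embryo2 = pd.DataFrame(
        {name: config.feature_marginals[name].sample(rng, n) for name in EMBRYO_FEATURES}
    )
    if config.identical_det_embryos:
        embryo2 = embryo1.copy()

    eta1 = config.truth.log_odds(pd.concat([patient, embryo1], axis=1)) if n else np.array([])
    eta2 = config.truth.log_odds(pd.concat([patient, embryo2], axis=1)) if n else np.array([])

    u = rng.normal(0.0, config.latent_sd, n)
    implant1 = rng.random(n) < _sigmoid(eta1 + u)
    implant2 = (rng.random(n) < _sigmoid(eta2 + u)) & is_det
    counts = implant1.astype(int) + implant2.astype(int)

    # MCAR missingness, injected after outcomes are determined.
    for frame, active in ((patient, None), (embryo1, None), (embryo2, is_det)):
        for name in frame.columns:
            mask = rng.random(n) < config.missing_rate
            if active is not None:
                mask &= active
            frame.loc[mask, name] = np.nan

    records: list[TransferRecord] = []
    for i in range(n):
        pid = f"P{i:06d}"
        embryos = [EmbryoRecord(embryo_id=f"{pid}-e1", features=dict(embryo1.iloc[i]))]
        if is_det[i]:
            embryos.append(EmbryoRecord(embryo_id=f"{pid}-e2", features=dict(embryo2.iloc[i])))
        records.append(
            TransferRecord(
                patient_id=pid,
                patient=PatientRecord(dict(patient.iloc[i])),
                embryos=embryos,
                transfer_type="DET" if is_det[i] else "SET",
                implantation_count=int(counts[i]),
            )
        )
    return records


def _features_row(truth: TruthModel, patient: PatientRecord, embryo: EmbryoRecord) -> pd.DataFrame:
    row = {**patient.features, **embryo.features}
    table = pd.DataFrame([row])
    absent = [f for f in truth.required_features if f not in table.columns]
    if absent:
        raise ValueError(f"truth model requires non-missing features: {absent}")
    return table


def _quad_nodes(latent_sd: float) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(_QUAD_NODES)
    return math.sqrt(2.0) * latent_sd * nodes, weights / math.sqrt(math.pi)


def marginal_probability(truth: TruthModel, patient: PatientRecord, embryo: EmbryoRecord) -> float:
    """E_u[sigmoid(log-odds + u)] by Gauss–Hermite quadrature (64 nodes).

    This is the ground-truth oracle for a single embryo's implantation
    probability; it never imputes, so any missing required feature raises.
    """
    table = _features_row(truth, patient, embryo)
    eta = float(truth.log_odds(table)[0])
    if truth.latent_sd == 0:
        return float(_sigmoid(np.array([eta]))[0])
    u, w = _quad_nodes(truth.latent_sd)
    return float(np.sum(w * _sigmoid(eta + u)))


def joint_det_probabilities(
    truth: TruthModel,
    patient: PatientRecord,
    embryo_a: EmbryoRecord,
    embryo_b: EmbryoRecord,
) -> tuple[float, float, float]:
    """(P[0 implantations], P[1], P[2]) for a double transfer.

    The two embryos are conditionally independent given the shared latent u;
    integrating u out induces positive dependence, so P[2] exceeds the product
    of the marginals whenever latent_sd > 0 and equals it at latent_sd = 0.
    """
    eta_a = float(truth.log_odds(_features_row(truth, patient, embryo_a))[0])
    eta_b = float(truth.log_odds(_features_row(truth, patient, embryo_b))[0])
    if truth.latent_sd == 0:
        pa, pb = float(_sigmoid(np.array([eta_a]))[0]), float(_sigmoid(np.array([eta_b]))[0])
        return ((1 - pa) * (1 - pb), pa * (1 - pb) + pb * (1 - pa), pa * pb)
    u, w = _quad_nodes(truth.latent_sd)
    pa, pb = _sigmoid(eta_a + u), _sigmoid(eta_b + u)
    p0 = float(np.sum(w * (1 - pa) * (1 - pb)))
    p2 = float(np.sum(w * pa * pb))
    p1 = float(np.sum(w * (pa * (1 - pb) + pb * (1 - pa))))
    return (p0, p1, p2)


# --- configuration file round-trip (YAML) ---------------------------------


def _marginal_to_dict(m: Marginal) -> dict:
    if isinstance(m, ContinuousMarginal):
        return {
            "kind": "continuous",
            "mean": m.mean,
            "sd": m.sd,
            "lower": m.lower,
            "upper": m.upper,
            "integer": m.integer,
        }
    if isinstance(m, BinaryMarginal):
        return {"kind": "binary", "p": m.p}
    return {"kind": "categorical", "probs": list(m.probs)}


def _marginal_from_dict(d: dict) -> Marginal:
    kind = d.get("kind")
    if kind == "continuous":
        return ContinuousMarginal(
            mean=d["mean"],
            sd=d["sd"],
            lower=d["lower"],
            upper=d["upper"],
            integer=bool(d.get("integer", False)),
        )
    if kind == "binary":
        return BinaryMarginal(p=d["p"])
    if kind == "categorical":
        return CategoricalMarginal(probs=tuple(d["probs"]))
    raise ConfigurationError(f"feature_marginals: unknown marginal kind {kind!r}")


def save_generator_config(config: GeneratorConfig, path) -> None:
    doc = {
        "n_patients": config.n_patients,
        "det_fraction": config.det_fraction,
        "missing_rate": config.missing_rate,
        "seed": config.seed,
        "identical_det_embryos": config.identical_det_embryos,
        "feature_marginals": {
            name: _marginal_to_dict(m) for name, m in config.feature_marginals.items()
        },
        "truth": {
            "intercept": config.truth.intercept,
            "coefficients": dict(config.truth.coefficients),
            "latent_sd": config.truth.latent_sd,
            "nonlinear_terms": [
                {"conditions": [list(c) for c in t.conditions], "offset": t.offset}
                for t in config.truth.nonlinear_terms
            ],
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_generator_config(path, **overrides) -> GeneratorConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    truth_doc = doc["truth"]
    truth = TruthModel(
        intercept=float(truth_doc["intercept"]),
        coefficients={k: float(v) for k, v in truth_doc["coefficients"].items()},
        nonlinear_terms=tuple(
            NonlinearTerm(
                conditions=tuple((c[0], c[1], float(c[2])) for c in t["conditions"]),
                offset=float(t["offset"]),
            )
            for t in truth_doc.get("nonlinear_terms", [])
        ),
        latent_sd=float(truth_doc.get("latent_sd", 1.0)),
    )
    config = GeneratorConfig(
        n_patients=int(doc["n_patients"]),
        det_fraction=float(doc.get("det_fraction", DEFAULT_DET_FRACTION)),
        feature_marginals={
            name: _marginal_from_dict(d) for name, d in doc["feature_marginals"].items()
        },
        truth=truth,
        missing_rate=float(doc.get("missing_rate", 0.05)),
        seed=int(doc.get("seed", 0)),
        identical_det_embryos=bool(doc.get("identical_det_embryos", False)),
    )
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    return config
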