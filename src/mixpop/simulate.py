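"""Synthetic breast-cancer cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
trimodal Gaussian log2 expression distribution for the index gene, gene
blocks co-expressed with it only inside one sub-population, independent
noise genes, a background "absent gene" (SRY analogue), ER status linked
to the low-expression component, an ESR1 analogue driven by ER status,
treatment arms, and survival times whose hazard depends on the index gene
only in the chemotherapy arm, with censoring and competing non-cancer
deaths.

All randomness flows from one root seed through named substreams, so each
stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, ExpressionMatrix, PatientRecord, DEFAULT_INDEX_GENE

_STREAMS = {"mixture": 0, "genes": 1, "er": 2, "clinical": 3}

#: Fitted trimodal parameters for the full-cohort index-gene distribution
#: (weights from the per-component areas, means and SDs in log2 units).
TRIMODAL_WEIGHTS = (0.26, 0.38, 0.36)
TRIMODAL_MEANS = (6.25, 7.89, 10.58)
TRIMODAL_SDS = (0.39, 1.12, 0.86)


@dataclass
class SurvivalModel:
    """Constant-hazard survival model per treatment arm.

    Disease-death hazard for a patient with index-gene value x is
    ``baseline_rate * exp(slope_arm * (x - cohort mean))``; the slope is
    non-zero only in the chemotherapy arm by default, so the index gene
    predicts survival there and nowhere else.
    """

    baseline_rate: float = 0.06  # disease deaths / year at the cohort mean
    slopes: dict = field(
        default_factory=lambda: {
            "none": 0.0,
            "hormone_only": 0.0,
            "chemo_only": -0.35,
            "other": 0.0,
        }
    )


@dataclass
class SyntheticConfig:
    """Parameters of the generated cohort.

    Defaults reproduce the fitted full-cohort mixture (weights 26/38/36%,
    means 6.25/7.89/10.58, SDs 0.39/1.12/0.86 log2 units) at the original
    cohort size n = 1980.
    """

    n_patients: int = 1980
    component_weights: tuple = TRIMODAL_WEIGHTS
    component_means: tuple = TRIMODAL_MEANS
    component_sds: tuple = TRIMODAL_SDS
    n_corr_genes_low: int = 50
    n_corr_genes_high: int = 50
    corr_strength: float = 0.6
    n_null_genes: int = 200
    background_gene_mean: float = 5.4
    background_gene_sd: float = 0.3
    # P(ER negative | true low component), P(ER negative | otherwise)
    er_model: tuple = (0.7, 0.05)
    # (mean, sd) of the ESR1 analogue for ER-negative and ER-positive patients
    esr1_params: tuple = ((6.2, 0.7), (9.8, 0.9))
    treatment_probs: dict = field(
        default_factory=lambda: {
            "none": 0.26,
            "hormone_only": 0.52,
            "chemo_only": 0.19,
            "other": 0.03,
        }
    )
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    other_cause_death_rate: float = 0.015  # per year
    censor_horizon: float = 12.0  # administrative follow-up limit, years
    early_censor_fraction: float = 0.1
    index_gene: str = DEFAULT_INDEX_GENE
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.component_weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if len(self.component_means) != len(w) or len(self.component_sds) != len(w):
            raise ValueError("component parameter lengths differ")
        if np.any(np.asarray(self.component_sds, float) < 0):
            raise ValueError("component SDs must be non-negative")
        for p in (*self.er_model, self.early_censor_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        tp = sum(self.treatment_probs.values())
        if abs(tp - 1.0) > 1e-9:
            raise ValueError("treatment probabilities must sum to 1")
        if self.censor_horizon <= 5:
            raise ValueError("censoring horizon must exceed 5 years")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    key = _STREAMS[stream]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(key,))
    )


def sample_mixture(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw index-gene values and true component labels.

    Each patient's component is drawn from ``component_weights`` and the
    value from that component's normal distribution.
    """
    config.validate()
    rng = _rng(config, "mixture")
    k = len(config.component_weights)
    labels = rng.choice(k, size=config.n_patients, p=np.asarray(config.component_weights))
    means = np.asarray(config.component_means)[labels]
    sds = np.asarray(config.component_sds)[labels]
    values = rng.normal(means, sds)
    return values, labels


def sample_er_status(config: SyntheticConfig, true_labels: np.ndarray) -> np.ndarray:
    """ER status per patient; negativity is concentrated in the low component.

    Depends on the true component label (not the sampled value) so the
    low-ESR1/low-index cluster is clean. Uses a dedicated substream so
    expression and clinical generation agree on the same statuses.
    """
    rng = _rng(config, "er")
    p_neg = np.where(np.asarray(true_labels) == 0, config.er_model[0], config.er_model[1])
    negative = rng.random(len(true_labels)) < p_neg
    return np.where(negative, "negative", "positive")


def generate_expression(
    config: SyntheticConfig, values: np.ndarray, true_labels: np.ndarray
) -> ExpressionMatrix:
    """Build the full genes x patients matrix around the index-gene values.

    Low-block genes correlate with the index gene (target Pearson r =
    ``corr_strength``) only among patients whose true label is the low
    component, and are independent noise elsewhere; high-block genes do the
    same for the high component. Null genes are i.i.d. normal. One
    background gene mimics a transcript absent from every sample, and an
    ESR1 analogue is bimodal by ER status.
    """
    config.validate()
    rng = _rng(config, "genes")
    n = len(values)
    if len(true_labels) != n:
        raise ValueError("values and labels lengths differ")

    gene_ids = [config.index_gene]
    rows = [np.asarray(values, float)]

    def _block(n_genes: int, target_label: int, prefix: str) -> None:
        mask = np.asarray(true_labels) == target_label
        z = np.zeros(n)
        if mask.sum() >= 2 and np.std(values[mask]) > 0:
            z[mask] = (values[mask] - values[mask].mean()) / values[mask].std()
        r = config.corr_strength
        for g in range(n_genes):
            mu = rng.uniform(6.0, 10.0)
            sd = rng.uniform(0.7, 1.3)
            eps = rng.normal(size=n)
            latent = np.where(mask, r * z + np.sqrt(max(0.0, 1 - r * r)) * eps, eps)
            gene_ids.append(f"{prefix}{g + 1:03d}")
            rows.append(mu + sd * latent)

    _block(config.n_corr_genes_low, 0, "LOWB")
    _block(config.n_corr_genes_high, len(config.component_weights) - 1, "HIGHB")

    for g in range(config.n_null_genes):
        mu = rng.uniform(5.0, 11.0)
        gene_ids.append(f"NULL{g + 1:03d}")
        rows.append(rng.normal(mu, 1.0, size=n))

    gene_ids.append("SRY")
    rows.append(rng.normal(config.background_gene_mean, config.background_gene_sd, size=n))

    er = sample_er_status(config, true_labels)
    (neg_mu, neg_sd), (pos_mu, pos_sd) = config.esr1_params
    esr1 = np.where(
        er == "negative",
        rng.normal(neg_mu, neg_sd, size=n),
        rng.normal(pos_mu, pos_sd, size=n),
    )
    gene_ids.append("ESR1")
    rows.append(esr1)

    patient_ids = [f"P{i + 1:05d}" for i in range(n)]
    return ExpressionMatrix(gene_ids, patient_ids, np.vstack(rows))


def generate_clinical(
    config: SyntheticConfig, values: np.ndarray, true_labels: np.ndarray
) -> list[PatientRecord]:
    """Simulate treatment arms and overall survival.

    Disease death, other-cause death and early censoring are competing
    exponential/uniform event times; the earliest one becomes the observed
    outcome, truncated at the administrative horizon. Treatment assignment
    is independent of expression.
    """
    config.validate()
    rng = _rng(config, "clinical")
    n = len(values)
    er = sample_er_status(config, true_labels)

    arms = list(config.treatment_probs)
    arm_p = np.array([config.treatment_probs[a] for a in arms])
    treatment = rng.choice(arms, size=n, p=arm_p)

    centered = np.asarray(values) - np.mean(values)
    slopes = np.array([config.survival_model.slopes.get(t, 0.0) for t in treatment])
    rate = config.survival_model.baseline_rate * np.exp(slopes * centered)

    t_disease = np.where(rate > 0, rng.exponential(1.0, n) / np.maximum(rate, 1e-300), np.inf)
    ocr = config.other_cause_death_rate
    t_other = np.where(ocr > 0, rng.exponential(1.0, n) / max(ocr, 1e-300), np.inf)
    horizon = config.censor_horizon
    early = rng.random(n) < config.early_censor_fraction
    t_early = rng.random(n) * horizon  # remains inf for an infinite horizon
    t_early[np.isnan(t_early)] = np.inf
    t_censor = np.where(early, t_early, horizon)

    records = []
    for i in range(n):
        t = min(t_disease[i], t_other[i], t_censor[i])
        if t == t_disease[i]:
            outcome = "died_of_disease"
        elif t == t_other[i]:
            outcome = "died_other_cause"
        else:
            outcome = "alive_at_last_followup"
        age = float(np.clip(rng.normal(61.0, 12.0), 25.0, 95.0))
        size = float(rng.lognormal(np.log(22.0), 0.5))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                er_status=str(er[i]),
                treatment=str(treatment[i]),
                survival_time=float(t),
                outcome=outcome,
                age_at_diagnosis=round(age, 1),
                tumor_size=round(size, 1),
            )
        )
    return records


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Compose mixture sampling, expression and clinical generation."""
    values, labels = sample_mixture(config)
    expression = generate_expression(config, values, labels)
    clinical = generate_clinical(config, values, labels)
    return Cohort(expression=expression, clinical=clinical, index_gene=config.index_gene)
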