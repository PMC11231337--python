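"""Seeded synthetic ICI cohorts for end-to-end testing of the analysis stack.

The generative model places each patient on a latent EMT axis e ~ N(0, 1).
Epithelial signature genes load negatively on e, mesenchymal genes positively,
so the signed-KS EMT score is a consistent estimator of the latent axis.
PD-L1 expression shares correlation rho_p with e; patients above the cohort
median are PD-L1-high.  Response (PD vs PR), progression hazard, and the
immune-signature structure (CTL down, Treg/M2 up with e) depend on e only
within the PD-L1-high stratum — the stratum-restricted effect structure the
downstream analyses are meant to recover.  Survival is exponential with a
multiplicative hazard exp(gamma_h * e) in the PD-L1-high stratum and
independent exponential censoring calibrated so roughly ``censor_rate`` of
baseline patients are censored.

A companion IHC-style cohort draws integer H-scores (0-300) for Slug, Twist1,
vimentin (positive loading), E-cadherin (negative loading) and PD-L1 from the
same latent axis, plus a zero-inflated PD-L1 tumor proportion score.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import EMTSignature, ExpressionMatrix, ImmuneSignature, ValidationError

__all__ = [
    "SyntheticCohortConfig",
    "cohort_signatures",
    "generate_cohort",
    "generate_ihc_cohort",
]

_IMMUNE_COUPLING_SIGN = {"CTL": -1.0, "Treg": +1.0, "M1": 0.0, "M2": +1.0}
_IHC_MARKERS = {"slug": +1.0, "twist1": +1.0, "vimentin": +1.0, "ecadherin": -1.0}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of the generative model (all effects per unit latent EMT)."""

    n_patients: int = 234            # RNA-seq cohort size
    n_ihc_patients: int = 90         # IHC cohort size
    n_epi_genes: int = 145
    n_mes_genes: int = 170
    n_immune_genes: int = 20         # per immune signature (CTL/Treg/M1/M2)
    n_background_genes: int = 2000
    emt_loading: float = 1.0         # beta: +/- loading of arms on latent EMT (log2 units)
    noise_sd: float = 1.0            # per-gene residual sd (log2 units)
    pdl1_emt_corr: float = 0.2       # rho_p: corr(latent PD-L1, latent EMT)
    response_intercept: float = 0.0  # alpha: baseline log-odds of PD
    response_effect: float = 1.0     # gamma_r: log-odds of PD per unit e, PD-L1-high only
    hazard_effect: float = 0.8       # gamma_h: log hazard per unit e, PD-L1-high only
    immune_coupling: float = 0.8     # kappa: CTL -kappa, Treg/M2 +kappa, PD-L1-high only
    censor_rate: float = 0.3         # approximate baseline censoring fraction
    baseline_pfs_scale: float = 6.0  # months
    baseline_os_scale: float = 18.0  # months
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4 or self.n_ihc_patients < 4:
            raise ValidationError("cohorts need >= 4 patients")
        for name in ("n_epi_genes", "n_mes_genes", "n_immune_genes", "n_background_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("noise_sd", "baseline_pfs_scale", "baseline_os_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not -1.0 < self.pdl1_emt_corr < 1.0:
            raise ValidationError("pdl1_emt_corr must lie in (-1, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_names(config: SyntheticCohortConfig) -> dict[str, list[str]]:
    names = {
        "epi": [f"EPI_SIM_{i:04d}" for i in range(1, config.n_epi_genes + 1)],
        "mes": [f"MES_SIM_{i:04d}" for i in range(1, config.n_mes_genes + 1)],
        "bg": [f"BG_SIM_{i:04d}" for i in range(1, config.n_background_genes + 1)],
    }
    for sig in _IMMUNE_COUPLING_SIGN:
        names[sig] = [f"{sig.upper()}_SIM_{i:03d}" for i in range(1, config.n_immune_genes + 1)]
    return names


def cohort_signatures(config: SyntheticCohortConfig) -> tuple[EMTSignature, dict[str, ImmuneSignature]]:
    """Gene signatures matching the generator's gene naming, for downstream scoring."""
    names = _gene_names(config)
    emt = EMTSignature(name="simulated",
                       epithelial=tuple(names["epi"]),
                       mesenchymal=tuple(names["mes"]))
    immune = {
        sig: ImmuneSignature(name=sig, genes=tuple(names[sig]),
                             description="simulated cohort signature")
        for sig in _IMMUNE_COUPLING_SIGN
    }
    return emt, immune


def _simulate_clinical(rng: np.random.Generator, e: np.ndarray, high: np.ndarray,
                       config: SyntheticCohortConfig) -> dict[str, np.ndarray]:
    n = e.size
    lin = config.response_intercept + config.response_effect * e * high
    p_pd = 1.0 / (1.0 + np.exp(-lin))
    response = np.where(rng.random(n) < p_pd, "PD", "PR")
    hazard_mult = np.exp(config.hazard_effect * e * high)
    out: dict[str, np.ndarray] = {"response": response, "p_pd": p_pd, "hazard_mult": hazard_mult}
    for endpoint, scale in (("pfs", config.baseline_pfs_scale), ("os", config.baseline_os_scale)):
        event_time = rng.exponential(scale / hazard_mult)
        if config.censor_rate > 0:
            censor_scale = scale * (1.0 - config.censor_rate) / config.censor_rate
            censor_time = rng.exponential(censor_scale, size=n)
        else:
            censor_time = np.full(n, np.inf)
        out[f"{endpoint}_time"] = np.minimum(event_time, censor_time)
        out[f"{endpoint}_event"] = (event_time <= censor_time).astype(int)
    return out


def generate_cohort(config: SyntheticCohortConfig | None = None
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw one RNA-seq-style cohort: (expression, clinical table, ground truth)."""
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_patients
    names = _gene_names(config)

    e = rng.normal(size=n)
    rho = config.pdl1_emt_corr
    pdl1_latent = rho * e + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
    high = (pdl1_latent > np.median(pdl1_latent)).astype(float)

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    def add_block(block_names: list[str], loading_per_sample: np.ndarray) -> None:
        g = len(block_names)
        mu = rng.normal(5.0, 1.0, size=g)
        vals = mu[:, None] + loading_per_sample[None, :] + rng.normal(0.0, config.noise_sd, size=(g, n))
        blocks.append(vals)
        gene_ids.extend(block_names)

    add_block(names["epi"], -config.emt_loading * e)
    add_block(names["mes"], +config.emt_loading * e)
    for sig, sign in _IMMUNE_COUPLING_SIGN.items():
        add_block(names[sig], sign * config.immune_coupling * e * high)
    add_block(names["bg"], np.zeros(n))

    pdl1_expr = 5.0 + pdl1_latent
    blocks.append(pdl1_expr[None, :])
    gene_ids.append("CD274")

    sample_ids = [f"P{i:04d}" for i in range(1, n + 1)]
    matrix = ExpressionMatrix(pd.DataFrame(np.vstack(blocks), index=pd.Index(gene_ids, name="gene"),
                                           columns=sample_ids))

    clin = _simulate_clinical(rng, e, high, config)
    cohort = pd.DataFrame({
        "sample_id": sample_ids,
        "pdl1_expr": pdl1_expr,
        "response": clin["response"],
        "pfs_time": clin["pfs_time"],
        "pfs_event": clin["pfs_event"],
        "os_time": clin["os_time"],
        "os_event": clin["os_event"],
    })
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "latent_emt": e,
        "latent_pdl1": pdl1_latent,
        "pdl1_high": high.astype(int),
        "p_pd": clin["p_pd"],
        "hazard_mult": clin["hazard_mult"],
    })
    return matrix, cohort, truth


def generate_ihc_cohort(config: SyntheticCohortConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one IHC-style cohort: (clinical table with H-scores and TPS, ground truth)."""
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_ihc_patients

    e = rng.normal(size=n)
    rho = config.pdl1_emt_corr
    pdl1_latent = rho * e + np.sqrt(1.0 - rho**2) * rng.normal(size=n)

    # zero-inflated TPS: lowest ~35% of latent PD-L1 stain negative
    cut = np.quantile(pdl1_latent, 0.35)
    tps = np.where(
        pdl1_latent <= cut,
        0.0,
        np.clip(np.round(np.exp(1.2 * pdl1_latent + 2.5)), 1, 100),
    )
    high = (tps >= 1.0).astype(float)

    sample_ids = [f"I{i:04d}" for i in range(1, n + 1)]
    cohort = pd.DataFrame({"sample_id": sample_ids, "pdl1_tps": tps})
    for marker, sign in _IHC_MARKERS.items():
        raw = 150.0 + 55.0 * sign * e + rng.normal(0.0, 45.0, size=n)
        cohort[f"hscore_{marker}"] = np.clip(np.round(raw), 0, 300).astype(int)
    raw_pdl1 = 120.0 + 60.0 * pdl1_latent + rng.normal(0.0, 40.0, size=n)
    cohort["hscore_pdl1"] = np.clip(np.round(raw_pdl1), 0, 300).astype(int)

    clin = _simulate_clinical(rng, e, high, config)
    for col in ("response", "pfs_time", "pfs_event", "os_time", "os_event"):
        cohort[col] = clin[col]
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "latent_emt": e,
        "latent_pdl1": pdl1_latent,
        "pdl1_high": high.astype(int),
        "p_pd": clin["p_pd"],
        "hazard_mult": clin["hazard_mult"],
    })
    return cohort, truth
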