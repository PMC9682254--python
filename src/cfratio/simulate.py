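"""Synthetic cohorts with known latent infiltration fractions.

The generator emulates the statistical structure the CFR analysis
assumes, so every pipeline stage is testable against ground truth:

* per-sample latent CD8 and CAF infiltration fractions, positively
  correlated on the Gaussian scale (default correlation 0.4, emulating
  the moderate CAF-immune correlation seen in bulk tumor cohorts) and
  mapped through the logistic function so fractions live in (0, 1);
* an expression matrix in which each cell type's signature genes are
  shifted by its latent fraction (immune cell types share the CD8 latent
  as a common immune-infiltration axis; CAF genes follow the CAF
  latent), on top of Gaussian noise and a constant baseline, floored at
  zero;
* Weibull survival whose log hazard decreases with the latent CFR
  d = a_CD8 - a_CAF (gamma > 0 means a protective CFR), with uniform
  administrative censoring;
* a binary response whose log odds increase with d, plus an independent
  PD-L1 TPS axis that also carries response signal (so biomarker
  combination has something to gain, while CFR and TPS stay
  uncorrelated).

One global seed governs all draws through deterministically spawned
substreams; the same config always yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cfratio.signatures import IMMUNE_CELL_TYPES, GeneSignature, SignatureRegistry

DEFAULT_CELL_TYPES = (*IMMUNE_CELL_TYPES, "CAF")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (units in comments)."""

    n_samples: int = 500
    n_background_genes: int = 5000      # signature genes stay a small genome fraction
    signature_size: int = 30            # genes per cell-type block
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    rho: float = 0.4                    # latent Gaussian correlation (CD8, CAF)
    beta: float = 2.0                   # expression shift per unit latent fraction
    noise_sd: float = 1.0               # expression noise, same units as baseline
    baseline: float = 5.0               # background expression level
    latent_mean_cd8: float = 0.0        # Gaussian-scale latent means (panel varies these)
    latent_mean_caf: float = 0.0
    weibull_scale: float = 12.0         # months
    weibull_shape: float = 1.0          # 1 = exponential
    gamma: float = 2.0                  # log-hazard decrease per unit latent CFR
    censor_horizon: float = 36.0        # months; censoring ~ Uniform(0, horizon)
    eta0: float = -1.0                  # response log-odds intercept
    eta1: float = 3.0                   # response log-odds slope on latent CFR
    eta_tps: float = 1.0                # response log-odds slope on the TPS axis
    seed: int = 0

    def validate(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.beta < 0 or self.noise_sd <= 0:
            raise ValueError("beta must be >= 0 and noise_sd > 0")
        if self.n_samples < 2 or self.signature_size < 2:
            raise ValueError("need >= 2 samples and >= 2 genes per signature")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0 or self.censor_horizon <= 0:
            raise ValueError("Weibull scale/shape and censor horizon must be > 0")


def _gene_id(cell_type: str, i: int) -> str:
    return f"{cell_type.replace(' ', '_')}_g{i + 1:03d}"


def generating_registry(cfg: GeneratorConfig) -> SignatureRegistry:
    """The signatures matching the generated gene ids, one per cell type."""
    reg = SignatureRegistry()
    for ct in cfg.cell_types:
        genes = [_gene_id(ct, i) for i in range(cfg.signature_size)]
        reg.add(GeneSignature(ct, genes, source="synthetic generator"))
    return reg


def simulate_cohort(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: (expression genes x samples, clinical, latent truth)."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_latent, rng_expr, rng_surv, rng_resp = [np.random.default_rng(s) for s in ss.spawn(4)]
    n = cfg.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    cov = np.array([[1.0, cfg.rho], [cfg.rho, 1.0]])
    z = rng_latent.multivariate_normal(
        [cfg.latent_mean_cd8, cfg.latent_mean_caf], cov, size=n, method="cholesky"
    )
    a_cd8, a_caf = _sigmoid(z[:, 0]), _sigmoid(z[:, 1])
    d = a_cd8 - a_caf

    gene_ids: list[str] = []
    shifts: list[np.ndarray] = []
    for ct in cfg.cell_types:
        latent = a_caf if ct == "CAF" else a_cd8   # immune types share the immune axis
        for i in range(cfg.signature_size):
            gene_ids.append(_gene_id(ct, i))
            shifts.append(cfg.beta * latent)
    for i in range(cfg.n_background_genes):
        gene_ids.append(f"BG_g{i + 1:05d}")
        shifts.append(np.zeros(n))
    mean = cfg.baseline + np.vstack(shifts)
    expr = np.maximum(mean + rng_expr.normal(0.0, cfg.noise_sd, size=mean.shape), 0.0)
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)
    expression.index.name = "gene"

    # Weibull PH: H(t) = (t/scale)^shape * exp(-gamma * d)
    u = rng_surv.uniform(size=n)
    t_event = cfg.weibull_scale * (-np.log(u) * np.exp(cfg.gamma * d)) ** (1.0 / cfg.weibull_shape)
    c_admin = rng_surv.uniform(0.0, cfg.censor_horizon, size=n)
    time = np.minimum(t_event, c_admin)
    event = (t_event <= c_admin).astype(int)

    tps_latent = rng_resp.normal(size=n)
    p_resp = _sigmoid(cfg.eta0 + cfg.eta1 * d + cfg.eta_tps * tps_latent)
    response = rng_resp.binomial(1, p_resp)
    # RECIST labels: responders are PR; non-responders split SD/PD
    nonresp_sd = rng_resp.uniform(size=n) < 0.6
    recist = np.where(response == 1, "PR", np.where(nonresp_sd, "SD", "PD"))
    tps = 100.0 * _sigmoid(tps_latent)

    clinical = pd.DataFrame(
        {"time": time, "event": event, "response": response, "recist": recist, "tps": tps},
        index=pd.Index(samples, name="sample"),
    )
    truth = pd.DataFrame(
        {"z_cd8": z[:, 0], "z_caf": z[:, 1], "a_cd8": a_cd8, "a_caf": a_caf,
         "latent_cfr": d, "p_response": p_resp, "seed": cfg.seed},
        index=pd.Index(samples, name="sample"),
    )
    return expression, clinical, truth


def simulate_tumor_type_panel(
    cfgs: list[GeneratorConfig],
    orr_link=None,
    n_patients_per_type: int = 60,
) -> pd.DataFrame:
    """Per-tumor-type mean latent CFR and a binomial ORR draw.

    Each config generates an independent cohort; its mean latent CFR is
    fed through ``orr_link`` (default: the config's own response
    logistic, at TPS = 0) to give the response probability of an
    ``n_patients_per_type``-patient binomial ORR.  Emulates a panel of
    tumor types whose response rates track their typical CFR.
    """
    if len(cfgs) < 4:
        raise ValueError("need >= 4 tumor types")
    rows = []
    for i, cfg in enumerate(cfgs):
        _, _, truth = simulate_cohort(cfg)
        mean_cfr = float(truth["latent_cfr"].mean())
        link = orr_link if orr_link is not None else (
            lambda x, c=cfg: _sigmoid(c.eta0 + c.eta1 * x)
        )
        p = float(np.clip(link(mean_cfr), 0.0, 1.0))
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, i]).generate_state(1)[0])
        orr = rng.binomial(n_patients_per_type, p) / n_patients_per_type
        rows.append({"tumor_type": f"T{i + 1:02d}", "n": n_patients_per_type,
                     "mean_cfr": mean_cfr, "orr": orr})
    return pd.DataFrame(rows).set_index("tumor_type")


def default_panel_configs(
    n_types: int = 20, seed: int = 0, base: GeneratorConfig | None = None
) -> list[GeneratorConfig]:
    """Configs for a tumor-type panel: CD8 latent mean varies across types."""
    base = base if base is not None else GeneratorConfig(n_samples=80, n_background_genes=100)
    mus = np.linspace(-1.5, 1.5, n_types)
    return [
        replace(base, latent_mean_cd8=float(mu), seed=int((seed * 1000 + i) % (2**31)))
        for i, mu in enumerate(mus)
    ]
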