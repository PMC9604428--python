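"""Generative models for bilateral expression, qPCR tables, and traits.

The generator mirrors the structure the decomposition assumes.  Per gene i,
individual j (group k), on the log scale:

    u_ij = b_i + s_ij + e^L_ij
    v_ij = a * (b_i + s_ij + e^R_ij) + delta

* ``b_i`` — per-gene baseline (lognormal expression);
* ``s_ij`` — drive shared by both sides: environmental/upstream fluctuation
  hitting the whole individual, the source of *extrinsic* noise;
* ``e^L, e^R`` — independent side-local noise, the source of *intrinsic*
  noise (fluctuating asymmetry), with standard deviation
  side_noise_sd * group multiplier * individual multiplier;
* the per-individual multipliers are lognormal — a "global control
  variable" making some individuals noisier across all genes at once,
  which is exactly what subset-based estimation needs to detect;
* ``a`` and ``delta`` — directional multiplicative and additive asymmetry.

Closed-form moments (gene-wise centered): Var(u - v) = (1-a)^2 drive_sd^2
+ (1 + a^2) side^2 and, at a = 1, eta2_ext = 4 drive_sd^2 + 2 side^2 and
eta2_int = 2 side^2.  The truth record carries the generalized per-side
average intrinsic variance (1 + a^2) side^2, which reduces to 2 side^2 at
a = 1.

Default magnitudes follow the RT-qPCR regime of a three-group embryo
cohort: a 13-gene panel, groups of 11/12/12 individuals, left/right dCt
fluctuation SD ~0.59 (so side_noise_sd = 0.59/sqrt(2)), and technical
replicate noise such that SD(rep1 - rep2) = 0.135 (log2 cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import BilateralMatrix

__all__ = [
    "SimulationConfig",
    "simulate_bilateral_expression",
    "simulate_qpcr_dataset",
    "simulate_traits",
]

_DEFAULT_TRAITS = {
    # log-scale trait ~ Normal(alpha0 + alpha*log(eta_int), exp(beta0 + beta*log(eta_int)))
    "mass": {"alpha0": -0.75, "alpha": -0.10, "beta0": -2.6, "beta": 0.30},
    "plgf": {"alpha0": 4.8, "alpha": -0.50, "beta0": -1.5, "beta": 0.50},
}


@dataclass
class SimulationConfig:
    """Full generative specification; the seed fixes every output bit-exactly."""

    n_genes: int = 13
    n_individuals_per_group: tuple = (11, 12, 12)
    group_names: tuple = ("C57BL/6J", "NOD-SCID", "BALB/c")
    group_scale_multipliers: tuple = (1.0, 1.0, 1.0)
    gene_mean_mean: float = 10.0
    gene_mean_sd: float = 2.0
    drive_sd: float = 0.3
    side_noise_sd: float = 0.59 / np.sqrt(2.0)
    individual_dispersion: float = 0.2  # SD of per-individual log noise multipliers
    directional_additive: float = 0.0  # delta
    directional_multiplicative: float = 1.0  # a
    tech_rep_sd: float = 0.135 / np.sqrt(2.0)  # per-well; SD(rep1-rep2)=0.135
    trait_coeffs: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TRAITS.items()})
    litter_effect: float = -0.02  # per extra pup, on log mass
    log_base: str = "2"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_individuals_per_group) != len(self.group_scale_multipliers):
            raise ValueError("one scale multiplier per group required")
        if len(self.group_names) != len(self.n_individuals_per_group):
            raise ValueError("one name per group required")
        for nm, val in (
            ("gene_mean_sd", self.gene_mean_sd),
            ("drive_sd", self.drive_sd),
            ("side_noise_sd", self.side_noise_sd),
            ("individual_dispersion", self.individual_dispersion),
            ("tech_rep_sd", self.tech_rep_sd),
        ):
            if val < 0:
                raise ValueError(f"{nm} must be nonnegative")
        if self.directional_multiplicative <= 0:
            raise ValueError("multiplicative asymmetry must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_individuals_per_group"] = list(self.n_individuals_per_group)
        d["group_names"] = list(self.group_names)
        d["group_scale_multipliers"] = list(self.group_scale_multipliers)
        return d


def simulate_bilateral_expression(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[BilateralMatrix, dict]:
    """Sample a bilateral log-expression matrix and its generative truth.

    Returns the matrix plus a truth record with the per-individual side
    noise SDs and the closed-form noise components implied by the
    configuration (see module docstring for the moment identities).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    G = config.n_genes
    counts = list(config.n_individuals_per_group)
    N = int(sum(counts))
    a = config.directional_multiplicative
    delta = config.directional_additive

    groups = np.repeat(np.asarray(config.group_names, dtype=object), counts)
    mult_group = np.repeat(np.asarray(config.group_scale_multipliers, dtype=float), counts)
    sex = np.empty(N, dtype=object)
    off = 0
    for c in counts:
        sex[off:off + c] = np.where(np.arange(c) % 2 == 0, "M", "F")
        off += c

    b = rng.normal(config.gene_mean_mean, config.gene_mean_sd, size=G)
    mult_ind = np.exp(rng.normal(0.0, config.individual_dispersion, size=N))
    side_sd = config.side_noise_sd * mult_group * mult_ind  # per individual
    s = rng.normal(0.0, config.drive_sd, size=(G, N))
    e_left = rng.normal(0.0, 1.0, size=(G, N)) * side_sd
    e_right = rng.normal(0.0, 1.0, size=(G, N)) * side_sd

    core = b[:, None] + s
    u = core + e_left
    v = a * (core + e_right) + delta

    M = BilateralMatrix(
        gene_ids=[f"gene{i:04d}" for i in range(G)],
        left=u,
        right=v,
        log_base=config.log_base,  # type: ignore[arg-type]
        individual_ids=[f"embryo{j:03d}" for j in range(N)],
        group_labels=groups,
        sex_labels=sex,
    )
    truth = {
        "gene_means": b,
        "individual_multipliers": mult_ind,
        "side_noise_sd_per_individual": side_sd,
        # per-side-average intrinsic variance, (1 + a^2) * side^2
        "eta2_int_per_individual": (1.0 + a**2) * side_sd**2,
        "eta2_int_pooled_per_group": {
            name: float(np.mean((1.0 + a**2) * side_sd[groups == name] ** 2))
            for name in config.group_names
        },
        "eta2_ext_at_a1": 4.0 * config.drive_sd**2 + 2.0 * config.side_noise_sd**2,
        "rho": config.drive_sd**2
        / (config.drive_sd**2 + config.side_noise_sd**2)
        if (config.drive_sd**2 + config.side_noise_sd**2) > 0
        else float("nan"),
        "config": config.to_dict(),
    }
    return M, truth


def simulate_qpcr_dataset(
    config: SimulationConfig,
    panel_size: int = 13,
    reference_gene: str = "18S",
    ct_intercept: float = 35.0,
    reference_abundance: float = 25.0,
    reference_side_sd: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Sample a duplicate-well RT-qPCR Ct table for a bilateral cohort.

    Panel-gene log2 abundances come from :func:`simulate_bilateral_expression`;
    the reference gene is a highly expressed transcript with its own small
    bilateral fluctuation.  Higher abundance means a lower Ct
    (Ct = ct_intercept - log2 abundance); every well is measured twice with
    independent technical noise of SD ``config.tech_rep_sd``.

    Returns a long-format table with columns ``gene_id, individual_id,
    side, replicate, ct, group, sex`` plus the generative truth record.
    """
    if panel_size < 3:
        raise ValueError("panel must contain at least 3 genes")
    rng = np.random.default_rng(config.seed)
    cfg = SimulationConfig(**{**config.to_dict(), "n_genes": panel_size})
    M, truth = simulate_bilateral_expression(cfg, rng=rng)
    N = M.n_individuals

    ref_core = reference_abundance + rng.normal(0.0, 0.1, size=N)
    ref_left = ref_core + rng.normal(0.0, reference_side_sd, size=N)
    ref_right = ref_core + rng.normal(0.0, reference_side_sd, size=N)

    rows = []
    genes = list(M.gene_ids) + [reference_gene]
    for j in range(N):
        for side, mat, ref in (("L", M.left, ref_left), ("R", M.right, ref_right)):
            abundances = np.concatenate([mat[:, j], [ref[j]]])
            for g, ab in zip(genes, abundances):
                ct_true = ct_intercept - ab
                for rep in (1, 2):
                    rows.append(
                        {
                            "gene_id": g,
                            "individual_id": M.individual_ids[j],
                            "side": side,
                            "replicate": rep,
                            "ct": ct_true + rng.normal(0.0, cfg.tech_rep_sd),
                            "group": M.group_labels[j],
                            "sex": M.sex_labels[j],
                        }
                    )
    table = pd.DataFrame(rows)
    truth = dict(truth)
    truth["reference_gene"] = reference_gene
    return table, truth


def simulate_traits(
    eta_int_per_individual: Sequence[float],
    trait_coeffs: Optional[dict] = None,
    seed: int = 0,
    litter_effect: float = -0.02,
    individual_ids: Optional[list] = None,
) -> pd.DataFrame:
    """Sample traits whose location and scale both depend on intrinsic noise.

    For each trait, log(trait) ~ Normal(alpha0 + alpha * log(eta_int),
    exp(beta0 + beta * log(eta_int))).  Mass additionally carries a litter
    effect (``litter_effect`` per pup beyond the mean litter) with litter
    sizes uniform on 4..9; PLGF has no litter term.
    """
    eta = np.asarray(eta_int_per_individual, dtype=float)
    if np.any(eta <= 0) or not np.all(np.isfinite(eta)):
        raise ValueError("intrinsic noise values must be positive and finite")
    coeffs = trait_coeffs if trait_coeffs is not None else {k: dict(v) for k, v in _DEFAULT_TRAITS.items()}
    rng = np.random.default_rng(seed)
    n = eta.size
    log_eta = np.log(eta)

    litters = rng.integers(4, 10, size=n)

    def draw(tc: dict, extra: np.ndarray) -> np.ndarray:
        mu = tc["alpha0"] + tc["alpha"] * log_eta + extra
        sigma = np.exp(tc["beta0"] + tc["beta"] * log_eta)
        return np.exp(rng.normal(mu, sigma))

    mass = draw(coeffs["mass"], litter_effect * (litters - litters.mean()))
    plgf = draw(coeffs["plgf"], np.zeros(n))
    return pd.DataFrame(
        {
            "individual_id": individual_ids
            if individual_ids is not None
            else [f"embryo{j:03d}" for j in range(n)],
            "eta_int": eta,
            "mass_g": mass,
            "litter_size": litters,
            "plgf_pg_ml": plgf,
        }
    )
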