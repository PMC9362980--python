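"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the data the analysis modules consume, so all
tests run download-free:

* two-group log-scale expression experiments with planted log-fold-changes
  (``simulate_diffexp``),
* Level-4-style replicate z-score sets sharing a latent consensus with
  per-replicate noise (``simulate_replicates``),
* signature libraries of z-score/p-value signatures with planted
  positively-connected partners and perturbagen groupings
  (``simulate_library``).

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
call; a fixed seed gives identical output on every platform.  Planted
correlations are imposed on the z-score-scale effects from which both the
d vectors and the p-values derive, so the extreme-Pearson and weighted
correlation metrics both see the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ExpressionDataset
from .exceptions import ValidationError
from .aggregate import ReplicateSet
from .sigcore import Signature, SignatureLibrary

__all__ = [
    "SimSpec",
    "simulate_diffexp",
    "simulate_replicates",
    "simulate_library",
]


@dataclass
class SimSpec:
    """Bundle of generator settings, loadable from YAML for the CLI.

    Defaults describe a routine small perturbation experiment: an
    L1000-sized gene space for libraries, a thousand-gene two-group design
    with a 5% planted effect fraction, and five replicates with moderate
    replicate noise.
    """

    seed: int = 0
    n_genes: int = 1000
    n_per_group: int = 10
    n_affected: int = 50
    effect_size: float = 2.0
    noise_sigma: float = 1.0
    baseline_mean: float = 8.0
    baseline_sigma: float = 2.0
    n_replicates: int = 5
    replicate_sigma: float = 0.3
    library_genes: int = 978
    n_null: int = 999
    planted_rhos: Sequence[float] = field(default_factory=lambda: (0.9,))
    planted_groups: Sequence[tuple[int, float]] = field(default_factory=tuple)


def _z_to_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_diffexp(
    n_genes: int = 1000,
    n_per_group: int = 10,
    n_affected: int = 50,
    effect_size: float = 2.0,
    noise_sigma: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Two-group log-scale expression experiment with planted effects.

    Gene baselines are Normal(baseline_mean, baseline_sigma^2); the first
    ``n_affected`` randomly chosen genes receive ``effect_size`` added in
    group A; i.i.d. Normal(0, noise_sigma^2) noise is added throughout.
    Returns the dataset (group label in annotation column ``group``) and a
    truth table of affected genes (empty when effect_size == 0).
    """
    if n_affected > n_genes:
        raise ValidationError("more affected genes than genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    baseline = rng.normal(baseline_mean, baseline_sigma, size=n_genes)
    affected = rng.choice(n_genes, size=n_affected, replace=False) if effect_size != 0 else np.array([], dtype=int)
    n_s = 2 * n_per_group
    X = baseline[:, None] + rng.normal(0.0, noise_sigma, size=(n_genes, n_s))
    X[affected[:, None], np.arange(n_per_group)] += effect_size
    sample_ids = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    ann = pd.DataFrame(
        {"group": ["A"] * n_per_group + ["B"] * n_per_group},
        index=pd.Index(sample_ids),
    )
    truth = pd.DataFrame(
        {"gene_id": genes[np.sort(affected)], "effect": effect_size}
    )
    ds = ExpressionDataset(
        gene_ids=genes, X=X, sample_ids=sample_ids, sample_annotations=ann,
        meta={"simulated": True, "seed": seed},
    )
    return ds, truth


def simulate_replicates(
    n_genes: int = 500,
    n_replicates: int = 5,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[ReplicateSet, np.ndarray]:
    """Replicate z-scores = latent consensus (standard normal) + noise.

    Returns the replicate set and the latent consensus vector.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    latent = rng.normal(size=n_genes)
    Z = latent[:, None] + rng.normal(0.0, noise_sigma, size=(n_genes, n_replicates))
    reps = ReplicateSet(
        gene_ids=genes,
        Z=Z,
        replicate_ids=[f"rep{i}" for i in range(n_replicates)],
        meta={"simulated": True, "seed": seed, "noise_sigma": noise_sigma},
    )
    return reps, latent


def simulate_library(
    n_genes: int = 978,
    n_null: int = 999,
    planted_rhos: Sequence[float] = (0.9,),
    planted_groups: Sequence[tuple[int, float]] = (),
    seed: int = 0,
) -> tuple[Signature, SignatureLibrary, pd.DataFrame]:
    """Signature library with planted partners of a query signature.

    The query's gene effects are standard-normal z-scores.  Each entry of
    ``planted_rhos`` adds one signature whose effects are bivariate-normal
    with the query at correlation rho; each ``(size, rho)`` in
    ``planted_groups`` adds ``size`` such signatures sharing one perturbagen.
    Null signatures are independent standard normal.  Per-gene p-values are
    the two-sided normal tails of the effects.  Every null signature is its
    own perturbagen.

    Returns (query, library, plant_table); the plant table lists each
    planted signature's id, perturbagen and target correlation.
    """
    for rho in list(planted_rhos) + [r for _, r in planted_groups]:
        if not 0.0 <= rho <= 1.0:
            raise ValidationError(f"planted correlation must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    q_eff = rng.normal(size=n_genes)
    query = Signature(
        gene_ids=genes, d=q_eff, p=_z_to_p(q_eff),
        meta={"signature_id": "query", "signature_type": "user"},
    )

    sigs: list[Signature] = []
    rows: list[dict] = []

    def planted_effects(rho: float) -> np.ndarray:
        return rho * q_eff + np.sqrt(1.0 - rho * rho) * rng.normal(size=n_genes)

    for i, rho in enumerate(planted_rhos):
        sid = f"plant_{i:03d}"
        eff = planted_effects(rho)
        sigs.append(Signature(genes, eff, _z_to_p(eff),
                              meta={"signature_id": sid, "perturbagen": sid,
                                    "signature_type": "CP"}))
        rows.append({"signature_id": sid, "perturbagen": sid, "rho": rho})
    for gi, (size, rho) in enumerate(planted_groups):
        pert = f"plantgroup_{gi:02d}"
        for j in range(size):
            sid = f"{pert}_m{j:02d}"
            eff = planted_effects(rho)
            sigs.append(Signature(genes, eff, _z_to_p(eff),
                                  meta={"signature_id": sid, "perturbagen": pert,
                                        "signature_type": "CP"}))
            rows.append({"signature_id": sid, "perturbagen": pert, "rho": rho})
    for i in range(n_null):
        sid = f"null_{i:04d}"
        eff = rng.normal(size=n_genes)
        sigs.append(Signature(genes, eff, _z_to_p(eff),
                              meta={"signature_id": sid, "perturbagen": sid,
                                    "signature_type": "CP"}))

    meta = pd.DataFrame(
        {"signature_id": [s.id for s in sigs],
         "perturbagen": [s.meta["perturbagen"] for s in sigs],
         "signature_type": "CP"}
    ).set_index("signature_id")
    library = SignatureLibrary(sigs, meta=meta)
    plant_table = pd.DataFrame(rows, columns=["signature_id", "perturbagen", "rho"])
    return query, library, plant_table
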