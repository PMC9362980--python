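"""Replicate-to-consensus aggregation.

Level-4-style replicate z-score matrices are combined into moderated
Z-score (MODZ) consensus signatures: each replicate is weighted by its mean
Spearman correlation with the other replicates (clipped below at 0.01,
then normalized to sum to one), and the consensus value per gene is the
weighted average of the replicate z-scores.  Reproducibility is assessed
with the distil_cc_q75 metric — the 75th percentile of pairwise Spearman
correlations — with a pass threshold of 0.2, exclusive.  Gene-wise p-values
compare the MODZ to zero with an empirical-Bayes weighted one-sample t-test
using the same weights.  Knockdown signatures targeting the same gene are
further aggregated into consensus gene signatures (CGS) by the identical
procedure, with the member d vectors as the replicate columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._eb import squeeze_variances
from .exceptions import ValidationError
from .sigcore import Signature, _as_str_array

__all__ = [
    "QC_THRESHOLD",
    "WEIGHT_CLIP",
    "ReplicateSet",
    "ConsensusSignature",
    "modz_weights",
    "modz",
    "distil_cc_q75",
    "eb_weighted_ttest",
    "build_consensus",
    "cgs_aggregate",
]

#: distil_cc_q75 pass threshold; a signature passes QC when its value is
#: strictly greater than this.
QC_THRESHOLD = 0.2

#: Floor applied to raw (mean-correlation) replicate weights before
#: normalization, so anti-correlated replicates keep a token weight.
WEIGHT_CLIP = 0.01


@dataclass
class ReplicateSet:
    """Genes x replicates matrix of z-scores destined for MODZ aggregation."""

    gene_ids: np.ndarray
    Z: np.ndarray
    replicate_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValidationError("replicate matrix must be 2-D (genes x replicates)")
        if self.Z.shape[0] != self.gene_ids.size:
            raise ValidationError("gene_ids length does not match replicate matrix rows")
        if self.Z.shape[1] != len(self.replicate_ids):
            raise ValidationError("replicate_ids length does not match matrix columns")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise ValidationError("duplicate replicate ids")
        if self.Z.shape[1] < 1:
            raise ValidationError("at least one replicate required")
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("non-finite values in replicate matrix")

    @property
    def n_replicates(self) -> int:
        return int(self.Z.shape[1])


@dataclass
class ConsensusSignature(Signature):
    """MODZ consensus with its replicate weights and reproducibility QC."""

    weights: np.ndarray | None = None
    qc_q75: float | None = None
    passed_qc: bool | None = None


def _spearman_matrix(Z: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations of replicate columns.

    Constant columns make Spearman undefined; those pairs are set to 0 with
    a warning rather than propagating NaN into the weights.
    """
    r = Z.shape[1]
    ranks = np.empty_like(Z)
    for j in range(r):
        ranks[:, j] = stats.rankdata(Z[:, j])
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ranks, rowvar=False)
    c = np.atleast_2d(c)
    if np.any(sd == 0):
        warnings.warn(
            "constant replicate column(s): undefined Spearman correlations set to 0",
            stacklevel=3,
        )
        bad = sd == 0
        c[bad, :] = 0.0
        c[:, bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def modz_weights(reps: ReplicateSet) -> np.ndarray:
    """Replicate weights for MODZ aggregation.

    One or two replicates get equal weights.  With three or more, each
    replicate's raw weight is the mean of its Spearman correlations with the
    other replicates, clipped below at ``WEIGHT_CLIP`` and normalized to sum
    to one.
    """
    r = reps.n_replicates
    if r <= 2:
        return np.full(r, 1.0 / r)
    c = _spearman_matrix(reps.Z)
    raw = (c.sum(axis=1) - 1.0) / (r - 1)  # mean off-diagonal correlation
    raw = np.clip(raw, WEIGHT_CLIP, None)
    return raw / raw.sum()


def modz(reps: ReplicateSet) -> ConsensusSignature:
    """Moderated Z-score consensus: the weighted average of replicates."""
    w = modz_weights(reps)
    values = reps.Z @ w
    q75 = distil_cc_q75(reps) if reps.n_replicates >= 2 else None
    return ConsensusSignature(
        gene_ids=reps.gene_ids,
        d=values,
        p=None,
        meta=dict(reps.meta),
        weights=w,
        qc_q75=q75,
        passed_qc=None if q75 is None else bool(q75 > QC_THRESHOLD),
    )


def distil_cc_q75(reps: ReplicateSet) -> float:
    """75th percentile of pairwise replicate Spearman correlations.

    Linear interpolation between order statistics (numpy's default
    percentile convention).  QC passes when the value exceeds
    ``QC_THRESHOLD`` strictly.
    """
    r = reps.n_replicates
    if r < 2:
        raise ValidationError("distil_cc_q75 needs at least 2 replicates")
    c = _spearman_matrix(reps.Z)
    iu = np.triu_indices(r, k=1)
    return float(np.percentile(c[iu], 75))


def eb_weighted_ttest(
    reps: ReplicateSet, weights: np.ndarray, prior_df: float | None = None
) -> np.ndarray:
    """Gene-wise p-values comparing MODZ to zero (EB weighted t-test).

    Per gene the weighted mean is the MODZ value and the weighted variance

        s_g^2 = sum_i w_i (Z_gi - MODZ_g)^2 / (1 - sum_i w_i^2)

    is unbiased under the sum-to-one weight normalization.  Variances are
    shrunk toward the fitted prior (see :mod:`sigconn._eb`); the moderated
    statistic is t_g = MODZ_g / sqrt(s_tilde_g^2 * sum_i w_i^2) on
    d0 + (R - 1) degrees of freedom, two-sided.

    ``prior_df=0`` disables moderation and reproduces the ordinary weighted
    one-sample t-test.
    """
    r = reps.n_replicates
    if r < 2:
        raise ValidationError("replicate inference needs at least 2 replicates")
    w = np.asarray(weights, dtype=float)
    if w.size != r or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValidationError("weights must be non-negative and sum to 1")
    sw2 = float(w @ w)
    mz = reps.Z @ w
    resid = reps.Z - mz[:, None]
    s2 = (resid * resid) @ w / (1.0 - sw2)
    df = r - 1.0
    s2_post, d0, _ = squeeze_variances(s2, df, prior_df=prior_df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mz / np.sqrt(s2_post * sw2)
    total_df = np.inf if np.isinf(d0) else d0 + df
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    return p


def build_consensus(
    reps: ReplicateSet, prior_df: float | None = None
) -> ConsensusSignature:
    """MODZ consensus with p-values and QC in one call.

    With a single replicate the consensus equals that replicate and carries
    no p-values ("no replicate inference") and no QC assessment.
    """
    cons = modz(reps)
    if reps.n_replicates >= 2:
        try:
            cons.p = eb_weighted_ttest(reps, cons.weights, prior_df=prior_df)
        except ValidationError:
            # identical replicates: no residual variance, no inference
            cons.meta["no_replicate_inference"] = True
    else:
        cons.meta["no_replicate_inference"] = True
    return cons


def cgs_aggregate(
    sigs: Sequence[Signature], prior_df: float | None = None
) -> ConsensusSignature:
    """Aggregate knockdown signatures of one target gene into a CGS.

    Member d vectors become the replicate columns of a :class:`ReplicateSet`
    and go through the MODZ + EB weighted t-test procedure.  All members
    must share a gene space and agree on ``target_gene`` metadata.
    """
    if not sigs:
        raise ValidationError("cgs_aggregate needs at least one signature")
    targets = {s.meta.get("target_gene") for s in sigs if s.meta.get("target_gene")}
    if len(targets) > 1:
        raise ValidationError(f"conflicting target genes: {sorted(targets)}")
    base = sigs[0]
    cols = [base.d]
    for s in sigs[1:]:
        if np.array_equal(s.gene_ids, base.gene_ids):
            cols.append(s.d)
        else:
            pos = {g: i for i, g in enumerate(s.gene_ids.tolist())}
            try:
                idx = np.array([pos[g] for g in base.gene_ids.tolist()], dtype=int)
            except KeyError as exc:
                raise ValidationError(
                    f"signature {s.id!r} is missing gene {exc.args[0]!r}"
                ) from None
            cols.append(s.d[idx])
    ids = [s.id or f"member_{i}" for i, s in enumerate(sigs)]
    reps = ReplicateSet(
        gene_ids=base.gene_ids,
        Z=np.column_stack(cols),
        replicate_ids=ids,
        meta={"target_gene": next(iter(targets), None), "members": ids},
    )
    cons = build_consensus(reps, prior_df=prior_df)
    if len(sigs) == 1 and base.p is not None:
        cons.p = base.p.copy()
    cons.meta["signature_type"] = "CGS"
    return cons
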