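"""Signature data model and connectivity metrics.

A perturbation *signature* pairs a vector of log-scale differential
expressions ``d`` with a vector of two-sided p-values ``p`` over a common
gene space.  Connectivity between a query and a library of signatures is
scored with a metric chosen by the query type:

========================  =======================================
query type                metric
========================  =======================================
library member signature  extreme Pearson of signed significances
uploaded full signature   weighted Pearson of the ``d`` vectors
up/down gene lists        Pearson against a +/-1 encoding
bare gene list            Random Set enrichment of -log10 p
========================  =======================================

Signed significance of gene *i* is ``sign(d_i) * (-log10 p_i)``; the
*extreme* signature keeps only the top-k and bottom-k signed significances
(k = 100 by default) and zeroes the rest, ties at the boundary retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateSetError,
    InsufficientInformationError,
    InsufficientOverlapError,
    NoOverlapError,
    ParameterError,
    QueryTypeError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "DEFAULT_TAIL_SIZE",
    "P_FLOOR",
    "Signature",
    "SignedSignificance",
    "ExtremeSignature",
    "UpDownQuery",
    "GeneListQuery",
    "ConnectivityResult",
    "SignatureLibrary",
    "signed_significance",
    "extreme_signature",
    "extreme_pearson",
    "weighted_correlation",
    "updown_correlation",
    "random_set_score",
    "connect_query",
]

#: Default tail size k for extreme signatures (top 100 / bottom 100 genes).
DEFAULT_TAIL_SIZE = 100

#: p-values are clipped below at this floor before -log10 so the signed
#: significance stays finite in double precision.
P_FLOOR = 1e-300


def _as_str_array(ids: Iterable[str]) -> np.ndarray:
    arr = np.asarray(list(ids) if not isinstance(ids, np.ndarray) else ids, dtype=object)
    return arr


def neglog10(p: np.ndarray) -> np.ndarray:
    """-log10(p) with the underflow floor applied."""
    return -np.log10(np.clip(np.asarray(p, dtype=float), P_FLOOR, None))


@dataclass
class Signature:
    """Differential-expression signature over an ordered gene space.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (opaque strings), length N.
    d
        Log-scale differential expression per gene (log2 ratio or z-score).
    p
        Two-sided p-value per gene in (0, 1]; ``None`` when the source
        provides only differential expressions.
    meta
        Free-form metadata (``signature_id``, ``perturbagen``,
        ``target_gene``, ``cell_line``, ``signature_type`` in
        {CP, CGS, OE, disease, user}).
    """

    gene_ids: np.ndarray
    d: np.ndarray
    p: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.gene_ids.shape != self.d.shape:
            raise ValidationError(
                f"gene_ids ({self.gene_ids.size}) and d ({self.d.size}) lengths differ"
            )
        if self.gene_ids.size == 0:
            raise ValidationError("empty signature")
        if len(set(self.gene_ids.tolist())) != self.gene_ids.size:
            raise ValidationError("duplicate gene identifiers in signature")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite differential expression values")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
            if self.p.shape != self.d.shape:
                raise ValidationError("p vector length differs from d")
            if np.any(~np.isfinite(self.p)) or np.any(self.p <= 0) or np.any(self.p > 1):
                raise ValidationError("p-values must lie in (0, 1]")

    @property
    def n_genes(self) -> int:
        return int(self.gene_ids.size)

    @property
    def id(self) -> str:
        return str(self.meta.get("signature_id", ""))

    def subset(self, idx: np.ndarray) -> "Signature":
        """Positional subset preserving order of ``idx``."""
        return Signature(
            gene_ids=self.gene_ids[idx],
            d=self.d[idx],
            p=None if self.p is None else self.p[idx],
            meta=dict(self.meta),
        )


@dataclass
class SignedSignificance:
    """Per-gene signed significance s_i = sign(d_i) * (-log10 p_i)."""

    gene_ids: np.ndarray
    s: np.ndarray


@dataclass
class ExtremeSignature:
    """Signed significances with all but the top-k/bottom-k zeroed."""

    gene_ids: np.ndarray
    e: np.ndarray
    k: int = DEFAULT_TAIL_SIZE


@dataclass
class UpDownQuery:
    """Directional query: sets of up- and downregulated gene identifiers."""

    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.up & self.down:
            raise ValidationError("up and down gene sets overlap")
        if not (self.up | self.down):
            raise ValidationError("up/down query is empty")


@dataclass
class GeneListQuery:
    """Undirected query: a bare set of gene identifiers."""

    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError("gene list query is empty")


@dataclass
class ConnectivityResult:
    """Score of one library signature against the query.

    ``score`` is a correlation in [-1, 1] for the correlation metrics and a
    standardized enrichment z for gene-list queries.  ``fdr`` is filled in by
    :func:`connect_query` (Benjamini-Hochberg across the queried library).
    """

    library_signature_id: str
    score: float
    p_value: float
    metric: Literal[
        "extreme_pearson", "weighted_correlation", "updown_correlation", "random_set"
    ]
    n_genes_used: int
    fdr: float | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# core transforms


def signed_significance(sig: Signature) -> SignedSignificance:
    """Signed significance vector of a signature.

    s_i = sign(d_i) * (-log10 p_i), so s_i = 0 whenever p_i = 1 and the sign
    of s_i follows the direction of differential expression.
    """
    if sig.p is None:
        raise QueryTypeError(
            "signature has no p-values; use the weighted-correlation path "
            "(weights from the library p-values only)"
        )
    s = np.sign(sig.d) * neglog10(sig.p)
    # sign(0) = 0 zeroes s for d == 0 regardless of p, which is the only
    # sensible reading of a directionless gene.
    return SignedSignificance(gene_ids=sig.gene_ids, s=s)


def extreme_signature(
    s: SignedSignificance | np.ndarray, k: int = DEFAULT_TAIL_SIZE
) -> ExtremeSignature:
    """Zero all signed significances other than the top-k and bottom-k.

    An entry survives when s_i >= s^k (the k-th most positive value) or
    s_i <= s^-k (the k-th most negative value); boundary ties are retained,
    so more than 2k nonzero entries are possible.  When N < 2k the vector is
    returned unchanged (every gene is "extreme") with a warning.
    """
    if k < 1:
        raise ParameterError(f"tail size k must be >= 1, got {k}")
    if isinstance(s, SignedSignificance):
        gene_ids, vec = s.gene_ids, np.asarray(s.s, dtype=float)
    else:
        vec = np.asarray(s, dtype=float)
        gene_ids = _as_str_array([f"g{i}" for i in range(vec.size)])
    n = vec.size
    if n < 2 * k:
        warnings.warn(
            f"signature has {n} genes < 2k = {2 * k}; extreme signature equals "
            "the full signed-significance vector",
            stacklevel=2,
        )
        return ExtremeSignature(gene_ids=gene_ids, e=vec.copy(), k=k)
    srt = np.sort(vec)
    upper = srt[n - k]  # k-th most positive
    lower = srt[k - 1]  # k-th most negative
    e = np.where((vec >= upper) | (vec <= lower), vec, 0.0)
    return ExtremeSignature(gene_ids=gene_ids, e=e, k=k)


# ---------------------------------------------------------------------------
# alignment and correlation helpers


def _align(a_ids: np.ndarray, b_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices into a and b selecting their gene-space intersection.

    Fast path: identical orderings map to themselves.  Otherwise exact-match
    intersection (identifiers are case-normalized at load time).
    """
    if a_ids is b_ids or (a_ids.size == b_ids.size and np.array_equal(a_ids, b_ids)):
        idx = np.arange(a_ids.size)
        return idx, idx
    _, ia, ib = np.intersect1d(a_ids, b_ids, return_indices=True)
    return ia, ib


def _corr_pvalue(r: float, n: float) -> float:
    """Two-sided p for a correlation via the t-transform with n-2 df."""
    if n <= 2 or not np.isfinite(r):
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return P_FLOOR
    t = r * np.sqrt((n - 2.0) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2.0)
    return float(min(max(p, P_FLOOR), 1.0))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise UndefinedCorrelationError(
            f"zero variance (var_x={vx:.3g}, var_y={vy:.3g}); correlation undefined"
        )
    return float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted Pearson correlation and its effective sample size.

    The effective sample size is the reciprocal of the null variance of r
    conditional on the weights and the centered magnitudes, obtained by
    randomizing the signs of the per-gene products:

        n_eff = (sum w x^2)(sum w y^2) / sum w^2 x^2 y^2

    (x, y centered by their weighted means).  It reduces to about the gene
    count for equal weights and stays calibrated when the weights are
    functions of the scored values themselves, as -log10 p weights are;
    the Kish size (sum w)^2 / sum w^2 ignores that coupling and
    overstates the information in the correlation.
    """
    sw = float(w.sum())
    xc = x - float(w @ x) / sw
    yc = y - float(w @ y) / sw
    vx = float(w @ (xc * xc))
    vy = float(w @ (yc * yc))
    if vx == 0.0 or vy == 0.0:
        raise UndefinedCorrelationError("zero weighted variance; correlation undefined")
    r = float(np.clip(float(w @ (xc * yc)) / np.sqrt(vx * vy), -1.0, 1.0))
    denom = float((w * w) @ (xc * xc * yc * yc))
    n_eff = vx * vy / denom if denom > 0 else float(w.size)
    return r, n_eff


# ---------------------------------------------------------------------------
# the four connectivity metrics


def extreme_pearson(
    a: Signature,
    b: Signature,
    k: int = DEFAULT_TAIL_SIZE,
    extreme_support: Literal["all", "union_nonzero"] = "all",
) -> ConnectivityResult:
    """Extreme Pearson correlation of signed significances.

    Both signatures must carry p-values.  Gene spaces are intersected, signed
    significances computed, tails of size ``k`` kept, and a standard Pearson
    correlation taken over the intersected space (zeros included by default;
    ``extreme_support="union_nonzero"`` restricts to genes extreme in at
    least one signature).
    """
    if a.p is None or b.p is None:
        raise QueryTypeError("extreme Pearson requires p-values on both signatures")
    ia, ib = _align(a.gene_ids, b.gene_ids)
    if ia.size < 3:
        raise InsufficientOverlapError(
            f"only {ia.size} shared genes; need at least 3"
        )
    sa = np.sign(a.d[ia]) * neglog10(a.p[ia])
    sb = np.sign(b.d[ib]) * neglog10(b.p[ib])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ea = extreme_signature(SignedSignificance(a.gene_ids[ia], sa), k=k).e
        eb = extreme_signature(SignedSignificance(b.gene_ids[ib], sb), k=k).e
    if extreme_support == "union_nonzero":
        keep = (ea != 0) | (eb != 0)
        ea, eb = ea[keep], eb[keep]
        if ea.size < 3:
            raise InsufficientOverlapError(
                f"only {ea.size} genes in the nonzero union; need at least 3"
            )
    n_used = int(ea.size)
    r = _pearson(ea, eb)
    return ConnectivityResult(
        library_signature_id=b.id,
        score=r,
        p_value=_corr_pvalue(r, n_used),
        metric="extreme_pearson",
        n_genes_used=n_used,
    )


def weighted_correlation(query: Signature, lib: Signature) -> ConnectivityResult:
    """Weighted Pearson correlation of two differential-expression vectors.

    Per-gene weights are the product of the two -log10 p-values; when the
    query carries no p-values the weights reduce to -log10 of the library
    p-values alone.  Genes with zero weight drop out.  The two-sided p-value
    uses the t-transform with the effective sample size n_eff =
    (sum w)^2 / sum w^2 in place of the gene count.
    """
    if lib.p is None:
        raise QueryTypeError("library signature lacks p-values; cannot weight")
    iq, il = _align(query.gene_ids, lib.gene_ids)
    if iq.size < 3:
        raise InsufficientOverlapError(f"only {iq.size} shared genes; need at least 3")
    wl = neglog10(lib.p[il])
    w = neglog10(query.p[iq]) * wl if query.p is not None else wl
    nz = w > 0
    if not nz.any():
        raise InsufficientInformationError("all correlation weights are zero")
    x = query.d[iq][nz]
    y = lib.d[il][nz]
    r, n_eff = _weighted_pearson(x, y, w[nz])
    note = ""
    if n_eff <= 2:
        p, note = 1.0, "n_eff<=2"
    else:
        p = _corr_pvalue(r, n_eff)
    return ConnectivityResult(
        library_signature_id=lib.id,
        score=r,
        p_value=p,
        metric="weighted_correlation",
        n_genes_used=int(nz.sum()),
        note=note,
    )


def updown_correlation(query: UpDownQuery, lib: Signature) -> ConnectivityResult:
    """Correlation of a +/-1 up/down encoding with a signature's d vector.

    The score is the Pearson correlation between the +/-1 vector and ``d``
    over matched genes.  Its significance is computed as the two-sided
    equal-variance two-sample t-test comparing ``d`` between up- and
    downregulated genes (the point-biserial equivalence).  If one side has
    no genes in the signature, the query degrades to the Random Set
    gene-list metric with a warning.
    """
    id_to_pos = {g: i for i, g in enumerate(lib.gene_ids.tolist())}
    up_idx = np.array(sorted(id_to_pos[g] for g in query.up if g in id_to_pos), dtype=int)
    dn_idx = np.array(sorted(id_to_pos[g] for g in query.down if g in id_to_pos), dtype=int)
    n_matched = up_idx.size + dn_idx.size
    if n_matched < 2 or up_idx.size == 0 or dn_idx.size == 0:
        warnings.warn(
            "up/down query does not cover both directions in the signature; "
            "falling back to the Random Set gene-list metric",
            stacklevel=2,
        )
        return random_set_score(
            GeneListQuery(query.up | query.down), lib
        )
    x = np.concatenate([np.ones(up_idx.size), -np.ones(dn_idx.size)])
    y = np.concatenate([lib.d[up_idx], lib.d[dn_idx]])
    r = _pearson(x, y)
    if n_matched < 3:
        p, note = 1.0, "too few genes for a t-test"
    else:
        # point-biserial: the t-transform of r on n-2 df is algebraically the
        # pooled equal-variance two-sample t-test of d between up and down
        p, note = _corr_pvalue(r, n_matched), ""
    return ConnectivityResult(
        library_signature_id=lib.id,
        score=r,
        p_value=p,
        metric="updown_correlation",
        n_genes_used=int(n_matched),
        note=note,
    )


def random_set_score(query: GeneListQuery, lib: Signature) -> ConnectivityResult:
    """Random Set enrichment of high significance within a gene list.

    Each gene is scored g_i = -log10 p_i; the statistic is the mean score of
    the matched query genes, standardized by the closed-form mean and
    variance of the mean score of a uniformly random set of the same size.
    The reported score is the standardized z; the p-value is the two-sided
    normal tail.
    """
    from . import enrich  # local import; enrich builds on sigcore elsewhere

    if lib.p is None:
        raise QueryTypeError("gene-list connectivity requires signature p-values")
    members = frozenset(query.genes) & set(lib.gene_ids.tolist())
    m = len(members)
    if m == 0:
        raise NoOverlapError("query gene list shares no gene with the signature")
    if m == lib.n_genes:
        raise DegenerateSetError("query gene list covers the whole signature gene space")
    g = neglog10(lib.p)
    mask = np.isin(lib.gene_ids, list(members))
    z, p = enrich.random_set_z_from_mask(g, mask, tail="two-sided")
    return ConnectivityResult(
        library_signature_id=lib.id,
        score=z,
        p_value=p,
        metric="random_set",
        n_genes_used=m,
    )


# ---------------------------------------------------------------------------
# libraries and query dispatch


class SignatureLibrary:
    """Indexed collection of signatures over a harmonized gene space.

    Gene spaces are harmonized to their intersection at construction (so
    correlation metrics never see missing values); per-signature dropped-gene
    counts are recorded in ``dropped_genes``.
    """

    def __init__(self, signatures: Sequence[Signature], meta=None):
        if not signatures:
            raise ValidationError("empty signature library")
        ids = [s.id or f"sig_{i}" for i, s in enumerate(signatures)]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate signature_id values in library")
        common = signatures[0].gene_ids
        identical = True
        for s in signatures[1:]:
            if not np.array_equal(common, s.gene_ids):
                identical = False
                common = np.intersect1d(common, s.gene_ids)
        if np.asarray(common).size < 3:
            raise ValidationError("library gene-space intersection has fewer than 3 genes")
        if not identical:
            common = np.sort(np.asarray(common, dtype=object))
        self.gene_ids = np.asarray(common, dtype=object)
        self.signature_ids = ids
        self.dropped_genes: dict[str, int] = {}
        aligned: list[Signature] = []
        for sid, s in zip(ids, signatures):
            if identical:
                a = s
            else:
                pos = {g: i for i, g in enumerate(s.gene_ids.tolist())}
                idx = np.array([pos[g] for g in self.gene_ids.tolist()], dtype=int)
                a = s.subset(idx)
            a.meta.setdefault("signature_id", sid)
            self.dropped_genes[sid] = s.n_genes - a.n_genes
            aligned.append(a)
        # every aligned signature now shares the common gene ordering
        self.signatures = aligned
        self.meta = meta

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def __getitem__(self, signature_id: str) -> Signature:
        try:
            i = self.signature_ids.index(signature_id)
        except ValueError:
            raise KeyError(signature_id) from None
        return self.signatures[i]

    def __contains__(self, signature_id: str) -> bool:
        return signature_id in self.signature_ids


QueryInput = Signature | UpDownQuery | GeneListQuery


def _infer_query_type(query: QueryInput, library: SignatureLibrary) -> str:
    if isinstance(query, UpDownQuery):
        return "updown"
    if isinstance(query, GeneListQuery):
        return "genelist"
    if isinstance(query, Signature):
        if query.id and query.id in library and query.p is not None:
            return "precomputed"
        return "signature" if query.p is not None else "diffexp"
    raise QueryTypeError(f"unsupported query object of type {type(query).__name__}")


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def connect_query(
    query: QueryInput,
    library: SignatureLibrary,
    k: int = DEFAULT_TAIL_SIZE,
    query_type: str | None = None,
) -> list[ConnectivityResult]:
    """Score a query against every library signature and rank the results.

    Metric dispatch by query type: a library-member signature uses extreme
    Pearson; an uploaded full signature (with or without p-values) uses the
    weighted correlation; up/down lists use the +/-1 correlation; bare gene
    lists use Random Set enrichment.  Benjamini-Hochberg FDR is computed
    across the result set, which is sorted by p-value ascending with |score|
    descending and signature id as deterministic tie-breaks.
    """
    qtype = query_type or _infer_query_type(query, library)
    if qtype in ("signature", "diffexp", "precomputed") and not isinstance(query, Signature):
        raise QueryTypeError(f"query type {qtype!r} requires a Signature object")
    if qtype == "updown" and not isinstance(query, UpDownQuery):
        raise QueryTypeError("query type 'updown' requires an UpDownQuery")
    if qtype == "genelist" and not isinstance(query, GeneListQuery):
        raise QueryTypeError("query type 'genelist' requires a GeneListQuery")

    results: list[ConnectivityResult] = []
    if qtype == "precomputed":
        for libsig in library:
            results.append(extreme_pearson(query, libsig, k=k))
    elif qtype in ("signature", "diffexp"):
        for libsig in library:
            results.append(weighted_correlation(query, libsig))
    elif qtype == "updown":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for libsig in library:
                results.append(updown_correlation(query, libsig))
    elif qtype == "genelist":
        for libsig in library:
            results.append(random_set_score(query, libsig))
    else:
        raise QueryTypeError(f"unknown query type {qtype!r}")

    fdr = _bh_fdr(np.array([r.p_value for r in results]))
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.p_value, -abs(r.score), r.library_signature_id))
    return results
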