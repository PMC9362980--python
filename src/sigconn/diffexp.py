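"""Signature construction from two-group expression matrices.

A signature contrasts a treatment group against a baseline group of samples
in a log-scale expression matrix: the differential expression is the
difference of group means and the gene-wise pooled variance is moderated
with the same empirical-Bayes shrinkage used for replicate aggregation,
giving a moderated t-statistic on d0 + n_a + n_b - 2 degrees of freedom.
Confounders are handled by filtering samples before the contrast, not by
covariate regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._eb import squeeze_variances
from .exceptions import ValidationError
from .sigcore import Signature, _as_str_array

__all__ = ["ExpressionDataset", "filter_samples", "create_signature"]

SampleSelector = Sequence[str] | Mapping[str, object] | Callable[[pd.Series], bool]


@dataclass
class ExpressionDataset:
    """Log-scale expression matrix (genes x samples) with sample annotations.

    ``sample_annotations`` is a DataFrame indexed by sample id; annotation
    keys are free-form (group labels, cell line, confounder levels).
    """

    gene_ids: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    sample_annotations: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (self.gene_ids.size, len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{self.gene_ids.size} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.gene_ids.tolist())) != self.gene_ids.size:
            raise ValidationError("duplicate gene ids")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("non-finite expression values")
        if self.sample_annotations is None:
            self.sample_annotations = pd.DataFrame(index=pd.Index(self.sample_ids))
        else:
            self.sample_annotations = self.sample_annotations.loc[self.sample_ids]
        if _looks_like_counts(self.X):
            warnings.warn(
                "matrix looks like raw counts (integer-valued, max > 50); "
                "log-scale input expected — consider log2(CPM + 1)",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _looks_like_counts(X: np.ndarray) -> bool:
    return bool(X.size and X.max() > 50 and np.allclose(X, np.round(X)))


def _resolve_selector(ds: ExpressionDataset, selector: SampleSelector) -> list[str]:
    ann = ds.sample_annotations
    if callable(selector):
        return [s for s in ds.sample_ids if selector(ann.loc[s])]
    if isinstance(selector, Mapping):
        for key in selector:
            if key not in ann.columns:
                raise ValidationError(f"unknown annotation key {key!r}")
        keep = np.ones(ds.n_samples, dtype=bool)
        for key, value in selector.items():
            keep &= (ann[key] == value).to_numpy()
        return [s for s, k in zip(ds.sample_ids, keep) if k]
    missing = set(selector) - set(ds.sample_ids)
    if missing:
        raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")
    return [s for s in ds.sample_ids if s in set(selector)]


def filter_samples(ds: ExpressionDataset, selector: SampleSelector) -> ExpressionDataset:
    """Subset samples by annotation predicate, id list, or key=value map.

    The applied filter is recorded in the output's ``meta["filters"]`` for
    provenance.  An empty selection is an error.
    """
    keep = _resolve_selector(ds, selector)
    if not keep:
        raise ValidationError("sample filter selected no samples")
    idx = [ds.sample_ids.index(s) for s in keep]
    meta = dict(ds.meta)
    meta.setdefault("filters", [])
    meta["filters"] = list(meta["filters"]) + [repr(selector)]
    return ExpressionDataset(
        gene_ids=ds.gene_ids,
        X=ds.X[:, idx],
        sample_ids=keep,
        sample_annotations=ds.sample_annotations.loc[keep],
        meta=meta,
    )


def create_signature(
    ds: ExpressionDataset,
    group_a: SampleSelector,
    group_b: SampleSelector,
    prior_df: float | None = None,
    meta: dict | None = None,
) -> Signature:
    """Two-group moderated-t signature: treatment (A) minus baseline (B).

    Per gene, d_g is the difference of group means; the pooled variance on
    n_a + n_b - 2 df is shrunk toward the empirical-Bayes prior, and the
    two-sided p-value uses the moderated t on d0 + n_a + n_b - 2 df.
    Genes with zero pooled variance take the prior variance.

    ``prior_df=0`` disables moderation (ordinary pooled two-sample t-test).
    """
    a = _resolve_selector(ds, group_a)
    b = _resolve_selector(ds, group_b)
    if set(a) & set(b):
        raise ValidationError("treatment and baseline groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >= 2 samples per group (got {len(a)} and {len(b)}); "
            "no variance estimate otherwise"
        )
    ia = [ds.sample_ids.index(s) for s in a]
    ib = [ds.sample_ids.index(s) for s in b]
    Xa, Xb = ds.X[:, ia], ds.X[:, ib]
    na, nb = len(ia), len(ib)
    d = Xa.mean(axis=1) - Xb.mean(axis=1)
    df = na + nb - 2.0
    ssa = ((Xa - Xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((Xb - Xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / df
    s2_post, d0, _ = squeeze_variances(s2, df, prior_df=prior_df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / se
    total_df = np.inf if np.isinf(d0) else d0 + df
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    out_meta = {
        "signature_type": "user",
        "group_a": list(a),
        "group_b": list(b),
        "n_a": na,
        "n_b": nb,
        "prior_df": d0,
        **(meta or {}),
        **({"filters": ds.meta["filters"]} if "filters" in ds.meta else {}),
    }
    return Signature(gene_ids=ds.gene_ids, d=d, p=p, meta=out_meta)
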