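"""Random Set enrichment and perturbagen-level connectivity.

The Random Set statistic standardizes the mean score of a member set
against the exact moments of the mean score of a uniformly random set of
the same size drawn without replacement from the universe:

    mu      = mean of all G scores
    sigma_m^2 = ((G - m) / (G - 1)) * sigma^2 / m

with sigma^2 the population variance of the scores.  The same closed form
drives both the gene-list connectivity metric (two-sided tail) and the
perturbagen connectivity analysis, which asks whether the connectivity
scores of all signatures of one perturbagen are unusually high as a set
(upper tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateSetError, NoOverlapError, ValidationError
from . import sigcore
from .sigcore import P_FLOOR, QueryInput, SignatureLibrary

__all__ = [
    "ScoredUniverse",
    "PerturbagenConnectivity",
    "random_set_z",
    "random_set_z_from_mask",
    "perturbagen_connectivity",
]


@dataclass
class ScoredUniverse:
    """Universe of scored items: a statistic per item, unique item ids."""

    item_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.item_ids = np.asarray(self.item_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.item_ids.size != self.scores.size:
            raise ValidationError("item_ids and scores lengths differ")
        if len(set(self.item_ids.tolist())) != self.item_ids.size:
            raise ValidationError("duplicate item ids in scored universe")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite scores in universe")


@dataclass
class PerturbagenConnectivity:
    """Set-level connectivity of one perturbagen's signatures to the query."""

    perturbagen_id: str
    z: float
    p_value: float
    member_count: int
    member_scores: tuple[float, float, float]  # (min, median, max) raw scores
    fdr: float | None = None


def random_set_z_from_mask(
    scores: np.ndarray, member_mask: np.ndarray, tail: Literal["upper", "two-sided"]
) -> tuple[float, float]:
    """Standardized Random Set statistic for a boolean member mask.

    Returns (z, p).  A constant score vector gives z = 0, p = 1 by
    convention.  p is the normal upper tail for ``tail="upper"`` and the
    two-sided normal tail otherwise, floored away from zero.
    """
    g = np.asarray(scores, dtype=float)
    n = g.size
    m = int(member_mask.sum())
    if m == 0:
        raise NoOverlapError("member set is empty")
    if m == n:
        raise DegenerateSetError("member set equals the whole universe")
    mu = g.mean()
    var = g.var()  # population variance
    if var == 0.0:
        return 0.0, 1.0
    xbar = g[member_mask].mean()
    z = (xbar - mu) * np.sqrt(m * (n - 1.0) / ((n - m) * var))
    p = stats.norm.sf(z) if tail == "upper" else 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(max(p, P_FLOOR), 1.0))


def random_set_z(
    universe: ScoredUniverse,
    member_ids: Sequence[str] | frozenset,
    tail: Literal["upper", "two-sided"] = "upper",
) -> tuple[float, float]:
    """Random Set z and p for a member set named by item id."""
    mask = np.isin(universe.item_ids, list(member_ids))
    return random_set_z_from_mask(universe.scores, mask, tail=tail)


def perturbagen_connectivity(
    query: QueryInput,
    library: SignatureLibrary,
    grouping: Mapping[str, str],
    k: int = sigcore.DEFAULT_TAIL_SIZE,
    query_type: str | None = None,
    signed: bool = False,
) -> list[PerturbagenConnectivity]:
    """Rank perturbagens by set-level connectivity of their signatures.

    Individual connectivity scores between the query and every library
    signature form the universe; each perturbagen's signatures form a member
    set tested with the upper-tail Random Set statistic.  By default the
    universe scores are |score| (connectivity strength regardless of sign);
    ``signed=True`` ranks concordant connections instead.  BH FDR is
    computed across perturbagens; output sorted by p ascending with z
    descending and perturbagen id as tie-breaks.

    ``grouping`` maps every library signature_id to exactly one perturbagen.
    """
    missing = [sid for sid in library.signature_ids if sid not in grouping]
    if missing:
        raise ValidationError(
            f"{len(missing)} library signatures missing from the perturbagen "
            f"grouping map (first: {missing[0]!r})"
        )
    results = sigcore.connect_query(query, library, k=k, query_type=query_type)
    sig_ids = np.array([r.library_signature_id for r in results], dtype=object)
    raw = np.array([r.score for r in results], dtype=float)
    scores = raw if signed else np.abs(raw)

    members: dict[str, list[int]] = {}
    for i, sid in enumerate(sig_ids.tolist()):
        members.setdefault(grouping[sid], []).append(i)

    out: list[PerturbagenConnectivity] = []
    for pert, idx in members.items():
        if not idx:  # pragma: no cover - grouping built from results
            warnings.warn(f"perturbagen {pert!r} has no signatures in the library")
            continue
        mask = np.zeros(scores.size, dtype=bool)
        mask[idx] = True
        if mask.all():
            raise DegenerateSetError(
                "a single perturbagen covers the whole library; set-level "
                "connectivity is undefined"
            )
        z, p = random_set_z_from_mask(scores, mask, tail="upper")
        mem = raw[idx]
        out.append(
            PerturbagenConnectivity(
                perturbagen_id=pert,
                z=z,
                p_value=p,
                member_count=len(idx),
                member_scores=(float(mem.min()), float(np.median(mem)), float(mem.max())),
            )
        )
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(np.array([r.p_value for r in out]), method="fdr_bh")[1]
    for r, q in zip(out, fdr):
        r.fdr = float(q)
    out.sort(key=lambda r: (r.p_value, -r.z, r.perturbagen_id))
    return out
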