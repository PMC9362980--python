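"""Text-format readers and writers: GCT, GMT, signature TSV, libraries.

All identifiers are treated as opaque strings and case-normalized to upper
case at load time so downstream gene-space intersection is exact-match.
No binary formats (GCTX/HDF5) are supported.

Dialects
--------
signature TSV   header ``gene_id<TAB>log2fc<TAB>p_value`` (p column optional)
up/down TSV     header ``gene_id<TAB>direction`` with direction +1/-1
GMT             ``name<TAB>description<TAB>gene...``; an up/down query is a
                pair of lines sharing a prefix with ``_UP``/``_DN`` suffixes
grouping TSV    ``signature_id<TAB>perturbagen_id<TAB>target_gene``
manifest        TSV (or YAML list) with columns signature_id, path and
                optional perturbagen, target_gene, cell_line, signature_type
results TSV     ``signature_id metric score p_value fdr n_genes_used``
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .diffexp import ExpressionDataset
from .enrich import PerturbagenConnectivity
from .exceptions import ParseError, ValidationError
from .sigcore import ConnectivityResult, Signature, SignatureLibrary, UpDownQuery

__all__ = [
    "GeneSet",
    "LibraryManifest",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_signature_tsv",
    "write_signature_tsv",
    "read_updown_tsv",
    "read_updown_gmt",
    "read_grouping_tsv",
    "write_grouping_tsv",
    "read_manifest",
    "load_library",
    "write_library",
    "write_results_tsv",
    "write_perturbagen_results_tsv",
]


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


def _norm(gene_id: str) -> str:
    return gene_id.strip().upper()


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# GCT


def read_gct(path: str | Path) -> ExpressionDataset:
    """Read a GCT 1.2 or 1.3 text matrix into an ExpressionDataset.

    The version line must be ``#1.2`` or ``#1.3``; declared dimensions are
    checked against the parsed body and 1.3 row/column metadata is captured
    into gene/sample annotations.  Parse errors name the offending line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise ParseError(f"{path}:1: expected '#1.2' or '#1.3', got {version!r}")
    dims = lines[1].split("\t") if len(lines) > 1 else []
    try:
        if version == "#1.2":
            n_genes, n_samples = int(dims[0]), int(dims[1])
            n_rmeta, n_cmeta = 0, 0
        else:
            n_genes, n_samples, n_rmeta, n_cmeta = (int(x) for x in dims[:4])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:2: malformed dimension line {lines[1]!r}") from None
    header = lines[2].split("\t")
    # 1.2 headers are Name/Description + samples; 1.3 is id + rowmeta + samples
    n_lead = 2 if version == "#1.2" else 1 + n_rmeta
    sample_ids = [s.strip() for s in header[n_lead:]]
    if len(sample_ids) != n_samples:
        raise ParseError(
            f"{path}:3: header names {len(sample_ids)} samples, "
            f"dimension line declares {n_samples}"
        )
    rmeta_names = header[1:n_lead] if version == "#1.3" else ["Description"]

    col_meta: dict[str, list[str]] = {}
    body_start = 3 + n_cmeta
    for i in range(n_cmeta):
        ln = 3 + i
        fields = lines[ln].split("\t")
        if len(fields) != n_lead + n_samples:
            raise ParseError(f"{path}:{ln + 1}: column-metadata row has {len(fields)} fields")
        col_meta[fields[0]] = [v.strip() for v in fields[n_lead:]]

    gene_ids: list[str] = []
    row_meta: list[list[str]] = []
    values: list[list[float]] = []
    for ln in range(body_start, len(lines)):
        line = lines[ln]
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_lead + n_samples:
            raise ParseError(
                f"{path}:{ln + 1}: expected {n_lead + n_samples} fields, got {len(fields)}"
            )
        gene_ids.append(_norm(fields[0]))
        row_meta.append(fields[1:n_lead])
        try:
            values.append([float(v) for v in fields[n_lead:]])
        except ValueError:
            raise ParseError(f"{path}:{ln + 1}: non-numeric expression value") from None
    if len(gene_ids) != n_genes:
        raise ParseError(
            f"{path}: dimension line declares {n_genes} genes, body has {len(gene_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ParseError(f"{path}: duplicate gene identifiers")
    ann = pd.DataFrame(col_meta, index=pd.Index(sample_ids)) if col_meta else None
    meta: dict = {"gct_version": version.lstrip("#"), "source": str(path)}
    if version == "#1.3" and n_rmeta:
        meta["gene_annotations"] = pd.DataFrame(
            row_meta, index=pd.Index(gene_ids), columns=rmeta_names
        )
    elif version == "#1.2":
        meta["gene_descriptions"] = [m[0] if m else "" for m in row_meta]
    return ExpressionDataset(
        gene_ids=np.array(gene_ids, dtype=object),
        X=np.array(values, dtype=float),
        sample_ids=sample_ids,
        sample_annotations=ann,
        meta=meta,
    )


def write_gct(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as GCT 1.3 when sample annotations exist, else 1.2."""
    path = Path(path)
    ann = ds.sample_annotations
    use_13 = ann is not None and ann.shape[1] > 0
    with path.open("w", encoding="utf-8") as fh:
        if use_13:
            fh.write("#1.3\n")
            fh.write(f"{ds.gene_ids.size}\t{ds.n_samples}\t0\t{ann.shape[1]}\n")
            fh.write("id\t" + "\t".join(ds.sample_ids) + "\n")
            for col in ann.columns:
                fh.write(col + "\t" + "\t".join(str(v) for v in ann[col]) + "\n")
            for g, row in zip(ds.gene_ids, ds.X):
                fh.write(str(g) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
        else:
            fh.write("#1.2\n")
            fh.write(f"{ds.gene_ids.size}\t{ds.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(ds.sample_ids) + "\n")
            descs = ds.meta.get("gene_descriptions") or [""] * ds.gene_ids.size
            for g, desc, row in zip(ds.gene_ids, descs, ds.X):
                fh.write(f"{g}\t{desc}\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT and gene lists


def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        genes = [_norm(g) for g in fields[2:] if g.strip()]
        if not genes:
            raise ParseError(f"{path}:{ln}: empty gene set {fields[0]!r}")
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=genes))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_updown_gmt(path: str | Path) -> UpDownQuery:
    """Build an up/down query from paired ``<prefix>_UP``/``<prefix>_DN`` GMT lines."""
    sets = {s.name.upper(): s for s in read_gmt(path)}
    ups = {n[:-3]: s for n, s in sets.items() if n.endswith("_UP")}
    dns = {n[:-3]: s for n, s in sets.items() if n.endswith("_DN")}
    shared = sorted(set(ups) & set(dns))
    if not shared:
        raise ParseError(f"{path}: no matching _UP/_DN gene-set pair")
    prefix = shared[0]
    return UpDownQuery(up=frozenset(ups[prefix].genes), down=frozenset(dns[prefix].genes))


def read_updown_tsv(path: str | Path) -> UpDownQuery:
    """Two-column TSV ``gene_id<TAB>direction`` with direction +1 or -1."""
    path = Path(path)
    up, down = set(), set()
    lines = path.read_text(encoding="utf-8").splitlines()
    start = 1 if lines and lines[0].lower().startswith("gene_id") else 0
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{ln}: expected 2 tab-separated fields")
        gene, direction = _norm(fields[0]), fields[1].strip()
        if direction in ("+1", "1"):
            up.add(gene)
        elif direction == "-1":
            down.add(gene)
        else:
            raise ParseError(f"{path}:{ln}: direction must be +1 or -1, got {direction!r}")
    return UpDownQuery(up=frozenset(up), down=frozenset(down))


# ---------------------------------------------------------------------------
# signature TSV


def read_signature_tsv(path: str | Path, meta: dict | None = None) -> Signature:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header[:2] != ["gene_id", "log2fc"]:
        raise ParseError(
            f"{path}:1: expected header 'gene_id\\tlog2fc[\\tp_value]', got {lines[0]!r}"
        )
    has_p = len(header) >= 3 and header[2] == "p_value"
    genes: list[str] = []
    d: list[float] = []
    p: list[float] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2 + has_p:
            raise ParseError(f"{path}:{ln}: too few fields")
        genes.append(_norm(fields[0]))
        try:
            d.append(float(fields[1]))
            if has_p:
                p.append(float(fields[2]))
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric value") from None
    m = dict(meta or {})
    m.setdefault("signature_id", path.stem)
    try:
        return Signature(
            gene_ids=np.array(genes, dtype=object),
            d=np.array(d),
            p=np.array(p) if has_p else None,
            meta=m,
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_signature_tsv(sig: Signature, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if sig.p is not None:
            fh.write("gene_id\tlog2fc\tp_value\n")
            for g, dv, pv in zip(sig.gene_ids, sig.d, sig.p):
                fh.write(f"{g}\t{_fmt(dv)}\t{_fmt(pv)}\n")
        else:
            fh.write("gene_id\tlog2fc\n")
            for g, dv in zip(sig.gene_ids, sig.d):
                fh.write(f"{g}\t{_fmt(dv)}\n")


# ---------------------------------------------------------------------------
# grouping map


def read_grouping_tsv(path: str | Path) -> dict[str, str]:
    """signature_id -> perturbagen_id map from a grouping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("signature_id", "perturbagen_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["signature_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate signature_id rows")
    return dict(zip(df["signature_id"], df["perturbagen_id"]))


def write_grouping_tsv(grouping: dict[str, str], path: str | Path,
                       target_genes: dict[str, str] | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("signature_id\tperturbagen_id\ttarget_gene\n")
        for sid, pert in grouping.items():
            tg = (target_genes or {}).get(sid, "")
            fh.write(f"{sid}\t{pert}\t{tg}\n")


# ---------------------------------------------------------------------------
# libraries


@dataclass
class LibraryManifest:
    """Resolved manifest: per-signature file paths and metadata rows."""

    paths: dict[str, Path]
    metadata: pd.DataFrame  # indexed by signature_id
    fingerprint: str = ""


def _fingerprint(gene_ids: Sequence[str]) -> str:
    h = hashlib.sha256("\n".join(sorted(map(str, gene_ids))).encode())
    return h.hexdigest()[:16]


def read_manifest(path: str | Path) -> LibraryManifest:
    """Read a library manifest (TSV or YAML); validate paths and uniqueness."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        rows = yaml.safe_load(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("signature_id", "path"):
        if col not in df.columns:
            raise ParseError(f"{path}: manifest missing column {col!r}")
    if df["signature_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate signature_id in manifest")
    paths: dict[str, Path] = {}
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.is_file():
            raise ParseError(f"{path}: manifest entry {row['signature_id']!r} "
                             f"points to missing file {p}")
        paths[row["signature_id"]] = p
    return LibraryManifest(paths=paths, metadata=df.set_index("signature_id"))


def load_library(source: str | Path | LibraryManifest) -> SignatureLibrary:
    """Load a signature library from a manifest, a manifest file or a directory.

    A directory is searched for ``manifest.tsv``/``manifest.yaml``; without
    one, every ``*.tsv`` file becomes a signature named by its stem.  Gene
    spaces are harmonized to the intersection; dropped-gene counts per
    signature are recorded on the returned library.
    """
    if isinstance(source, LibraryManifest):
        manifest = source
    else:
        source = Path(source)
        if source.is_dir():
            for name in ("manifest.tsv", "manifest.yaml", "manifest.yml"):
                if (source / name).is_file():
                    manifest = read_manifest(source / name)
                    break
            else:
                files = sorted(source.glob("*.tsv"))
                if not files:
                    raise ParseError(f"{source}: no manifest and no .tsv signatures")
                manifest = LibraryManifest(
                    paths={f.stem: f for f in files},
                    metadata=pd.DataFrame(index=pd.Index([f.stem for f in files],
                                                         name="signature_id")),
                )
        else:
            manifest = read_manifest(source)
    sigs = []
    for sid, p in manifest.paths.items():
        row = (manifest.metadata.loc[sid].dropna().to_dict()
               if sid in manifest.metadata.index else {})
        row.pop("path", None)
        sigs.append(read_signature_tsv(p, meta={"signature_id": sid, **row}))
    lib = SignatureLibrary(sigs, meta=manifest.metadata)
    manifest.fingerprint = _fingerprint(lib.gene_ids)
    return lib


def write_library(lib: SignatureLibrary, directory: str | Path) -> Path:
    """Write a library as one TSV per signature plus a manifest.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_cols = ("perturbagen", "target_gene", "cell_line", "signature_type")
    with (directory / "manifest.tsv").open("w", encoding="utf-8") as fh:
        fh.write("signature_id\tpath\t" + "\t".join(meta_cols) + "\n")
        for sig in lib:
            fname = f"{sig.id}.tsv"
            write_signature_tsv(sig, directory / fname)
            vals = [str(sig.meta.get(c, "")) for c in meta_cols]
            fh.write(f"{sig.id}\t{fname}\t" + "\t".join(vals) + "\n")
    return directory / "manifest.tsv"


# ---------------------------------------------------------------------------
# results


def write_results_tsv(results: Sequence[ConnectivityResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("signature_id\tmetric\tscore\tp_value\tfdr\tn_genes_used\n")
        for r in results:
            fh.write(
                f"{r.library_signature_id}\t{r.metric}\t{_fmt(r.score)}\t"
                f"{_fmt(r.p_value)}\t{_fmt(r.fdr if r.fdr is not None else 1.0)}\t"
                f"{r.n_genes_used}\n"
            )


def write_perturbagen_results_tsv(
    results: Sequence[PerturbagenConnectivity], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("perturbagen_id\tz\tp_value\tfdr\tn_signatures\n")
        for r in results:
            fh.write(
                f"{r.perturbagen_id}\t{_fmt(r.z)}\t{_fmt(r.p_value)}\t"
                f"{_fmt(r.fdr if r.fdr is not None else 1.0)}\t{r.member_count}\n"
            )
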