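"""Domain containers, file I/O, and configuration.

The pipeline moves three kinds of objects around: a gene-by-sample
expression matrix (log2-scale, FPKM-like), a per-sample clinical table
(cancer type, tumor/normal tissue class, optional survival and therapy
response), and named gene-symbol sets (GMT format).  Everything here is
thin validation and plumbing on top of pandas.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("netscreen")

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "AnalysisConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "align",
    "CLINICAL_COLUMNS",
    "DEFAULT_NET_SIGNATURE",
]

#: Canonical clinical-table columns.  ``time`` (days), ``event`` (0/1) and
#: ``response`` ({response, non_response}) are optional; ``time`` must be
#: present wherever ``event`` is.
CLINICAL_COLUMNS = ("sample", "cancer_type", "tissue", "time", "event", "response")

#: Bundled default NET signature: genes encoding major NET structural
#: components and NETosis drivers (granule proteases, antimicrobial
#: proteins, histone-citrullination machinery).  This is a partial
#: reconstruction assembled from genes commonly reported as NET
#: constituents; real analyses should supply the full signature explicitly
#: via a GMT file.
DEFAULT_NET_SIGNATURE = [
    "MPO", "ELANE", "CTSG", "PRTN3", "LTF", "LCN2", "CAMP", "DEFA1",
    "LYZ", "LCP1", "S100A8", "S100A9", "S100A12", "CAT", "AZU1", "BPI",
    "MMP8", "MMP9", "PADI4", "CEACAM8", "FCGR3B", "CXCR2", "ITGAM",
]


class ExpressionMatrix:
    """A gene-by-sample matrix of log2-scale expression values.

    Wraps a :class:`pandas.DataFrame` (rows = gene symbols, columns =
    sample ids) and enforces the container invariants: unique gene and
    sample identifiers, all values finite, and at least 2 genes and 2
    samples.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"expression matrix must be at least 2 genes x 2 samples, got {data.shape}"
            )
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self._data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self._data.loc[list(gene_ids)])

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._data.equals(other._data)


class GeneSetCollection(Mapping):
    """Named gene-symbol sets (signature, hallmark, marker, EMT programs).

    Mapping from set name to an ordered list of unique gene symbols.
    Symbols are case-sensitive plain strings; no alias resolution.
    """

    def __init__(self, sets: Mapping[str, list[str]]):
        clean: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            n_dup = 0
            for g in genes:
                if g in seen:
                    n_dup += 1
                else:
                    seen[g] = None
            if n_dup:
                warnings.warn(
                    f"gene set {name!r}: dropped {n_dup} duplicate symbol(s)",
                    stacklevel=2,
                )
            if name in clean:
                raise ValueError(f"duplicate gene set name {name!r}")
            clean[name] = list(seen)
        if not clean:
            raise ValueError("gene set collection is empty")
        self._sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def restrict_to(self, genes) -> "GeneSetCollection":
        """Intersect every set with ``genes``, dropping sets that empty out."""
        universe = set(genes)
        kept = {}
        for name, members in self._sets.items():
            hit = [g for g in members if g in universe]
            if hit:
                kept[name] = hit
            else:
                warnings.warn(f"gene set {name!r} has no genes in the matrix; dropped")
        return GeneSetCollection(kept)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and knobs for the screening cascade.

    Attributes
    ----------
    r_nrg : Pearson |R| threshold defining a NET-associated regulatory
        gene (NRG) pair within one cancer type.
    r_hallmark : |R| threshold for the hallmark/immune association screen
        (kept separate from ``r_nrg`` on purpose).
    p_sig : two-sided significance level used throughout.
    fc_min : linear-scale fold-change threshold for differential
        expression (|log2FC| >= log2(fc_min)).
    recurrence_min : minimum number of cancer types (within one survival
        class) in which a gene must form a qualifying pair to be "core".
    exclusive_in_min / exclusive_out_max : positive-pair counts defining
        class exclusivity (in >5 types of one class, in <2 of the other).
    n_quantile_groups : groups for quantile stratification of NET scores.
    perm_count : permutations for pre-ranked GSEA nulls.
    cutpoint_quantile_range : admissible quantile window for the
        maximally selected survival cutpoint.
    log2_transform : apply log2(x+1) on expression load (for raw FPKM).
    """

    r_nrg: float = 0.35
    r_hallmark: float = 0.30
    p_sig: float = 0.05
    fc_min: float = 2.0
    recurrence_min: int = 5
    exclusive_in_min: int = 6
    exclusive_out_max: int = 1
    n_quantile_groups: int = 4
    perm_count: int = 1000
    seed: int = 0
    cutpoint_quantile_range: tuple[float, float] = (0.10, 0.90)
    log2_transform: bool = False

    def __post_init__(self):
        for name in ("r_nrg", "r_hallmark", "p_sig", "fc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recurrence_min < 1:
            raise ValueError("recurrence_min must be >= 1")
        lo, hi = self.cutpoint_quantile_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("cutpoint_quantile_range must satisfy 0 < lo < hi < 1")
        if self.n_quantile_groups < 2:
            raise ValueError("n_quantile_groups must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutpoint_quantile_range" in raw:
            raw["cutpoint_quantile_range"] = tuple(raw["cutpoint_quantile_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cutpoint_quantile_range"] = list(d["cutpoint_quantile_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a tab-separated gene x sample expression table.

    First column holds gene symbols; the header row holds sample ids.
    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (logged).  Non-numeric cells and duplicate sample ids
    are errors.
    """
    path = Path(path)
    with open(path) as fh:
        line = "#"
        while line.startswith("#"):
            line = fh.readline()
    header = line.rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample id(s) in header: {dups}")

    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    raw.columns = sample_ids
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at gene {numeric.index[i]!r}, "
            f"sample {numeric.columns[j]!r}"
        )
    # re-parse through numpy for correctly rounded string -> float64
    numeric = pd.DataFrame(
        raw.to_numpy(dtype=float), index=raw.index, columns=raw.columns
    )

    if numeric.index.duplicated().any():
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        numeric = numeric.iloc[order]
        n_before = numeric.shape[0]
        numeric = numeric[~numeric.index.duplicated(keep="first")]
        # restore original first-appearance order of the surviving genes
        first_seen: dict[str, int] = {}
        for k, g in enumerate(raw.index):
            first_seen.setdefault(g, k)
        numeric = numeric.loc[sorted(numeric.index, key=first_seen.__getitem__)]
        logger.info(
            "collapsed %d duplicate gene row(s) by highest mean",
            n_before - numeric.shape[0],
        )
    if log2_transform:
        if (numeric.to_numpy() < 0).any():
            raise ValueError("log2_transform requires non-negative values")
        numeric = np.log2(numeric + 1.0)
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path, meta: str | None = None) -> None:
    """Write a tab-separated expression table (optionally with a ``#`` header comment)."""
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        expr.data.to_csv(fh, sep="\t", index_label="gene", float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in MSigDB GMT format: name, description, genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a clinical annotation table.

    Requires columns ``sample``, ``cancer_type``, ``tissue``; optional
    ``time`` (days, >= 0), ``event`` (0/1) and ``response``.  Any row with
    an event flag but no time is rejected.
    """
    table = table.copy()
    for col in ("sample", "cancer_type", "tissue"):
        if col not in table.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if table["sample"].duplicated().any():
        dups = table.loc[table["sample"].duplicated(), "sample"].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in clinical table: {dups[:5]}")
    bad_tissue = set(table["tissue"].dropna()) - {"tumor", "normal"}
    if bad_tissue:
        raise ValueError(f"tissue class must be 'tumor' or 'normal', got {bad_tissue}")
    for col in ("time", "event", "response"):
        if col not in table.columns:
            table[col] = np.nan
    table["time"] = pd.to_numeric(table["time"], errors="raise")
    table["event"] = pd.to_numeric(table["event"], errors="raise")
    if (table["time"].dropna() < 0).any():
        raise ValueError("negative survival time")
    ev = table["event"].dropna()
    if not ev.isin([0, 1]).all():
        raise ValueError("event flag must be 0 or 1")
    orphan = table["event"].notna() & table["time"].isna()
    if orphan.any():
        raise ValueError(
            f"{int(orphan.sum())} row(s) have an event flag but no survival time"
        )
    bad_resp = set(table["response"].dropna()) - {"response", "non_response"}
    if bad_resp:
        raise ValueError(f"response must be 'response'/'non_response', got {bad_resp}")
    return table.reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read a tab-separated clinical table (columns per :data:`CLINICAL_COLUMNS`)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    return validate_clinical(table)


def write_clinical(table: pd.DataFrame, path, meta: str | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def align(expr: ExpressionMatrix, clinical: pd.DataFrame):
    """Restrict expression and clinical table to their shared samples.

    Both outputs carry samples in the expression matrix's order; the
    intersection size is logged.  Idempotent.
    """
    shared = [s for s in expr.sample_ids if s in set(clinical["sample"])]
    if not shared:
        raise ValueError("expression matrix and clinical table share no samples")
    logger.info("aligned on %d shared sample(s)", len(shared))
    expr2 = expr.subset_samples(shared)
    clin2 = (
        clinical.set_index("sample").loc[shared].reset_index()
    )
    return expr2, clin2


def default_signature_collection() -> GeneSetCollection:
    """The bundled (partial) NET signature as a one-set collection."""
    return GeneSetCollection({"NET_SIGNATURE": DEFAULT_NET_SIGNATURE})
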