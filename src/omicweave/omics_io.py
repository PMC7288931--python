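"""Readers/writers for the tabular formats the pipeline consumes and emits.

All genomic coordinates are 1-based closed intervals (SEG convention).
Every on-disk format is plain TSV; missing methylation values are written
as the literal token ``NA``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("CNV", "MET_BETA", "EXPR_FPKM", "EXPR_COUNT")

REGION_CLASSES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Default mapping from MAF Variant_Classification to the silent/intronic flags.
DEFAULT_CLASSIFICATION_FLAGS: Mapping[str, tuple[bool, bool]] = {
    "Silent": (True, False),
    "Intron": (False, True),
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene record; ``tss`` follows the strand convention."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    gene_type: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_start > self.gene_end:
            raise ValidationError(f"{self.gene_id}: gene_start > gene_end")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end


class AnnotationSet:
    """An ordered, id-unique collection of :class:`GeneAnnotation`."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValidationError(
                f"duplicate gene ids: {list(dup[dup > 1].index[:5])}"
            )
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._by_id[gene_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "symbol": [g.symbol for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "gene_start": [g.gene_start for g in self.genes],
                "gene_end": [g.gene_end for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "gene_type": [g.gene_type for g in self.genes],
            }
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationSet) and self.genes == other.genes


SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "value"]


@dataclass
class SegmentTable:
    """Per-sample copy-number segments (segment mean on a log2-ratio scale)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"SegmentTable missing columns: {missing}")
        self.df = self.df[SEGMENT_COLUMNS].reset_index(drop=True)
        if len(self.df):
            if (self.df["start"] > self.df["end"]).any():
                bad = self.df.index[self.df["start"] > self.df["end"]][0]
                raise ValidationError(f"segment row {bad}: start > end")
            if (self.df["n_probes"] < 0).any():
                raise ValidationError("segment with negative probe count")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SegmentTable) and self.df.equals(other.df)


@dataclass
class ProbeManifest:
    """Methylation probe annotation: position, CpG-region class, gene links."""

    df: pd.DataFrame  # probe_id, chrom, pos, region_class, gene_ids (list)

    def __post_init__(self) -> None:
        required = ["probe_id", "chrom", "pos", "region_class", "gene_ids"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"ProbeManifest missing columns: {missing}")
        self.df = self.df[required].reset_index(drop=True)
        if self.df["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in manifest")
        bad = set(self.df["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValidationError(f"unknown region classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeManifest):
            return NotImplemented
        a = self.df.assign(gene_ids=self.df["gene_ids"].map(tuple))
        b = other.df.assign(gene_ids=other.df["gene_ids"].map(tuple))
        return a.equals(b)


class GeneMatrix:
    """A genes x samples numeric matrix tagged with its modality.

    Invariants enforced at construction:

    * ``MET_BETA`` values lie in [0, 1] where present; NaN permitted.
    * ``EXPR_COUNT`` values are nonnegative integers.
    * ``EXPR_FPKM`` values are nonnegative.
    * gene and sample labels are duplicate-free.
    """

    def __init__(self, modality: str, values: pd.DataFrame):
        if modality not in MODALITIES:
            raise ValidationError(f"unknown modality {modality!r}")
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if modality == "MET_BETA":
            present = ~np.isnan(arr)
            out = present & ((arr < 0) | (arr > 1))
            if out.any():
                cells = [
                    (values.index[i], values.columns[j])
                    for i, j in zip(*np.nonzero(out))
                ][:10]
                raise ValidationError(f"beta values outside [0,1] at {cells}")
        else:
            if np.isnan(arr).any():
                raise ValidationError(f"{modality} matrix contains missing values")
            if (arr < 0).any() and modality != "CNV":
                raise ValidationError(f"negative values in {modality} matrix")
            if modality == "EXPR_COUNT" and not np.array_equal(arr, np.round(arr)):
                raise ValidationError("non-integer values in count matrix")
        self.modality = modality
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "GeneMatrix":
        return GeneMatrix(self.modality, self.values.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Iterable[str]) -> "GeneMatrix":
        return GeneMatrix(self.modality, self.values[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneMatrix):
            return NotImplemented
        return (
            self.modality == other.modality
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
        )

    def __repr__(self) -> str:
        g, s = self.shape
        return f"GeneMatrix({self.modality}, {g} genes x {s} samples)"


@dataclass
class MutationTable:
    """Parsed somatic mutation records with silent/intronic flags."""

    df: pd.DataFrame  # sample_id, gene_id, variant_classification, is_silent, is_intronic

    def __post_init__(self) -> None:
        required = [
            "sample_id",
            "gene_id",
            "variant_classification",
            "is_silent",
            "is_intronic",
        ]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"MutationTable missing columns: {missing}")
        self.df = self.df[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MutationTable) and self.df.equals(other.df)


STAGES = ("I", "II", "III", "IV")
GRADES = ("G1", "G2", "G3", "G4")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, survival endpoints and extra scores."""

    df: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = ["os_time", "os_event", "pfs_time", "pfs_event"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"ClinicalTable missing columns: {missing}")
        for col in ("os_event", "pfs_event"):
            vals = set(self.df[col].dropna().unique())
            if not vals <= {0, 1}:
                raise ValidationError(f"{col} values outside {{0,1}}: {vals}")
        for col in ("os_time", "pfs_time"):
            if (self.df[col].dropna() < 0).any():
                raise ValidationError(f"negative {col}")
        for col, vocab in (("stage", STAGES), ("grade", GRADES)):
            if col in self.df.columns:
                bad = set(self.df[col].dropna().unique()) - set(vocab)
                if bad:
                    raise ValidationError(f"unknown {col} levels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ClinicalTable) and self.df.equals(other.df)


@dataclass
class SubtypeAssignment:
    """sample -> cluster labels plus the diagnostics that produced them."""

    labels: pd.Series  # index = sample ids, values = cluster label strings
    method: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValidationError("duplicate sample ids in assignment")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SubtypeAssignment) and self.labels.equals(
            other.labels
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_SEG_ALIASES = {
    "sample_id": ["sample_id", "sample", "id"],
    "chrom": ["chrom", "chromosome", "chr"],
    "start": ["start", "loc.start"],
    "end": ["end", "loc.end"],
    "n_probes": ["n_probes", "num_mark", "num.mark", "probes"],
    "value": ["value", "seg.mean", "segment_mean"],
}


def _resolve_columns(header: list[str], aliases: Mapping[str, list[str]]) -> dict:
    lower = {h.lower(): h for h in header}
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                resolved[canonical] = lower[name]
                break
        else:
            raise ParseError(f"missing column for {canonical!r} (header: {header})")
    return resolved


def read_segments(path: str | Path, dialect: str = "seg_tsv") -> SegmentTable:
    """Read a SEG-like TSV into a :class:`SegmentTable`.

    Every row is either parsed or rejected with an error naming the line;
    rows are never silently dropped.
    """
    if dialect != "seg_tsv":
        raise ValidationError(f"unknown segment dialect {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(list(raw.columns), _SEG_ALIASES)
    out = pd.DataFrame(
        {
            "sample_id": raw[cols["sample_id"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
        }
    )
    for key, caster in (("start", int), ("end", int), ("n_probes", int), ("value", float)):
        try:
            out[key] = raw[cols[key]].map(caster)
        except (TypeError, ValueError) as exc:
            bad = raw[cols[key]].map(
                lambda v: not _castable(v, caster)
            )
            line = int(raw.index[bad][0]) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}:{line}: malformed {key}: {exc}") from exc
    bad = out["start"] > out["end"]
    if bad.any():
        line = int(out.index[bad][0]) + 2
        raise ParseError(f"{path}:{line}: end < start")
    return SegmentTable(out)


def _castable(v, caster) -> bool:
    try:
        caster(v)
        return True
    except (TypeError, ValueError):
        return False


def read_gene_matrix(path: str | Path, modality: str) -> GeneMatrix:
    """Read a TSV with gene rows and sample columns; validate per-modality."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GeneMatrix(modality, df)


def read_maf(
    path: str | Path,
    classification_flags: Mapping[str, tuple[bool, bool]] = DEFAULT_CLASSIFICATION_FLAGS,
) -> MutationTable:
    """Read a MAF-like TSV; derive silent/intronic flags from the mapping."""
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    aliases = {
        "gene_id": ["hugo_symbol", "gene_id", "gene"],
        "sample_id": ["tumor_sample_barcode", "sample_id", "sample"],
        "variant_classification": ["variant_classification"],
    }
    cols = _resolve_columns(list(raw.columns), aliases)
    vc = raw[cols["variant_classification"]].astype(str)
    flags = vc.map(lambda v: classification_flags.get(v, (False, False)))
    return MutationTable(
        pd.DataFrame(
            {
                "sample_id": raw[cols["sample_id"]].astype(str),
                "gene_id": raw[cols["gene_id"]].astype(str),
                "variant_classification": vc,
                "is_silent": flags.map(lambda t: t[0]),
                "is_intronic": flags.map(lambda t: t[1]),
            }
        )
    )


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a BED-like annotation TSV (gene_id, symbol, chrom, strand, start, end, type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "symbol", "chrom", "strand", "gene_start", "gene_end", "gene_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"annotation missing columns: {missing}")
    return AnnotationSet(
        GeneAnnotation(
            gene_id=r.gene_id,
            symbol=r.symbol,
            chrom=r.chrom,
            strand=r.strand,
            gene_start=int(r.gene_start),
            gene_end=int(r.gene_end),
            gene_type=r.gene_type,
        )
        for r in df.itertuples()
    )


def read_probe_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["pos"] = df["pos"].astype(int)
    df["gene_ids"] = df["gene_ids"].fillna("").map(
        lambda s: [g for g in s.split(",") if g]
    )
    return ProbeManifest(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_tables(
    objects: Mapping[str, object], out_dir: str | Path, overwrite: bool = False
) -> dict[str, str]:
    """Write named result objects under ``out_dir``; return a name->path manifest.

    File names are deterministic functions of the object names. Reading a
    written file back yields an equal object (text round-trip at 10
    significant digits).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in objects.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        _write_one(obj, path)
        manifest[name] = str(path)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_one(obj: object, path: Path) -> None:
    if isinstance(obj, GeneMatrix):
        df = obj.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)
    elif isinstance(obj, SegmentTable):
        obj.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, MutationTable):
        obj.df.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, ClinicalTable):
        df = obj.df.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)
    elif isinstance(obj, SubtypeAssignment):
        out = obj.labels.rename("label").to_frame()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
    elif isinstance(obj, AnnotationSet):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, ProbeManifest):
        df = obj.df.copy()
        df["gene_ids"] = df["gene_ids"].map(",".join)
        df.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
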