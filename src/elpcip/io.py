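"""Domain containers and readers/writers for every external format the pipeline touches.

All tabular formats are plain TSV.  Sequence data is FASTA (handled through
Biopython, stored upper-case).  Genomic coordinates are converted at the
boundary: GFF3 and the InDel TSV dialect are 1-based inclusive on disk,
0-based half-open in memory.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ProbeMapEntry",
    "ProbeMap",
    "IntensityMatrix",
    "ExperimentDesign",
    "GeneModel",
    "IndelInterval",
    "PipelineConfig",
    "read_intensity_table",
    "read_design",
    "read_probe_map",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_indels",
    "write_indels",
    "read_annotations",
    "write_table",
    "read_table",
]

TREATMENT_LEVELS = ("control", "treated")
INDEL_KINDS = ("insertion", "deletion")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeMapEntry:
    """One probe's membership in a probe set."""

    probe_id: str
    probeset_id: str
    probe_index: int  # position of the probe within its set, >= 0


class ProbeMap:
    """Probe -> probe-set mapping with uniqueness invariants enforced.

    ``probe_id`` is unique across the map and ``probe_index`` is unique
    within a probe set.
    """

    def __init__(self, entries: Iterable[ProbeMapEntry]):
        self.entries: list[ProbeMapEntry] = list(entries)
        self._by_probe: dict[str, ProbeMapEntry] = {}
        self._by_set: dict[str, list[ProbeMapEntry]] = {}
        seen_index: set[tuple[str, int]] = set()
        for e in self.entries:
            if e.probe_index < 0:
                raise FormatError(f"negative probe_index for probe {e.probe_id!r}")
            if e.probe_id in self._by_probe:
                raise FormatError(f"duplicate probe_id {e.probe_id!r} in probe map")
            key = (e.probeset_id, e.probe_index)
            if key in seen_index:
                raise FormatError(
                    f"probe_index {e.probe_index} repeated within probe set {e.probeset_id!r}"
                )
            seen_index.add(key)
            self._by_probe[e.probe_id] = e
            self._by_set.setdefault(e.probeset_id, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe

    @property
    def probeset_ids(self) -> list[str]:
        return list(self._by_set)

    def probeset_of(self, probe_id: str) -> str:
        return self._by_probe[probe_id].probeset_id

    def probes_of(self, probeset_id: str) -> list[str]:
        return [e.probe_id for e in self._by_set[probeset_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [e.probe_id for e in self.entries],
                "probeset_id": [e.probeset_id for e in self.entries],
                "probe_index": [e.probe_index for e in self.entries],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class IntensityMatrix:
    """Probe-level fluorescence values: probes (rows) x arrays (columns).

    Values are positive, finite reals on the linear fluorescence scale.
    """

    probe_ids: list[str]
    array_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.array_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.array_ids)} arrays"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe_id in intensity matrix")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise FormatError("duplicate array_id in intensity matrix")
        bad = ~np.isfinite(self.values) | (self.values <= 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"non-positive or non-finite intensity at probe "
                f"{self.probe_ids[i]!r}, array {self.array_ids[j]!r}: {self.values[i, j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.array_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t", float_format="%.12g")

    def column_index(self, array_id: str) -> int:
        return self.array_ids.index(array_id)


class ExperimentDesign:
    """Array -> (genotype, treatment, replicate) assignment for a 2x2 factorial.

    The first genotype label encountered (file/row order) plays the reference
    "genotype A" role in downstream quadrant classification unless overridden.
    """

    def __init__(self, frame: pd.DataFrame, genotype_a: str | None = None):
        required = {"array_id", "genotype", "treatment", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise FormatError("design table is empty")
        if frame["array_id"].duplicated().any():
            dup = frame.loc[frame["array_id"].duplicated(), "array_id"].iloc[0]
            raise FormatError(f"duplicate array_id {dup!r} in design")
        bad_t = ~frame["treatment"].isin(TREATMENT_LEVELS)
        if bad_t.any():
            raise FormatError(
                f"treatment must be one of {TREATMENT_LEVELS}, "
                f"got {frame.loc[bad_t, 'treatment'].iloc[0]!r}"
            )
        genotypes = list(dict.fromkeys(frame["genotype"]))
        if len(genotypes) != 2:
            raise FormatError(f"expected exactly 2 genotypes, got {genotypes}")
        self.frame = frame.reset_index(drop=True).copy()
        self.frame["replicate"] = self.frame["replicate"].astype(int)
        if (self.frame["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive")
        self.genotypes: tuple[str, str] = tuple(genotypes)  # type: ignore[assignment]
        if genotype_a is not None:
            if genotype_a not in genotypes:
                raise FormatError(f"genotype_a {genotype_a!r} not present in design")
            other = [g for g in genotypes if g != genotype_a][0]
            self.genotypes = (genotype_a, other)

    @property
    def array_ids(self) -> list[str]:
        return list(self.frame["array_id"])

    @property
    def genotype_a(self) -> str:
        return self.genotypes[0]

    def cells(self) -> dict[tuple[str, str], list[str]]:
        """Map (genotype, treatment) -> array ids, in design row order."""
        out: dict[tuple[str, str], list[str]] = {}
        for row in self.frame.itertuples(index=False):
            out.setdefault((row.genotype, row.treatment), []).append(row.array_id)
        return out

    def require_balanced(self, min_replicates: int = 2) -> int:
        """Return the common per-cell replicate count r, or raise."""
        cells = self.cells()
        expected = {(g, t) for g in self.genotypes for t in TREATMENT_LEVELS}
        if set(cells) != expected:
            raise FormatError(
                f"design is not full factorial: cells present {sorted(cells)}"
            )
        sizes = {len(v) for v in cells.values()}
        if len(sizes) != 1:
            raise FormatError(f"unbalanced design: cell sizes {sorted(sizes)}")
        r = sizes.pop()
        if r < min_replicates:
            raise FormatError(f"need >= {min_replicates} replicates per cell, got {r}")
        return r

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneModel:
    """A gene span. Coordinates are 0-based half-open; strand is '+' or '-'."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class IndelInterval:
    """A small insertion/deletion. Coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"indel: invalid interval [{self.start}, {self.end})")
        if self.kind not in INDEL_KINDS:
            raise FormatError(f"indel kind must be one of {INDEL_KINDS}, got {self.kind!r}")


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across pipeline stages.

    alpha is the raw-p significance gate used probe-wise for each of the
    three ANOVA effects; min_core_probes is the per-set count of
    triple-significant probes required to call a core intersectional
    probe set; tgt is the per-array target trimmed-mean signal.
    """

    alpha: float = 0.01
    min_core_probes: int = 3
    tgt: float = 500.0
    max_mismatch: int = 0
    upstream_window: int = 1000
    motif_width: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_core_probes < 1:
            raise ValueError("min_core_probes must be >= 1")
        if self.tgt <= 0:
            raise ValueError("tgt must be positive")
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_intensity_table(path: str | Path) -> IntensityMatrix:
    """Read a probe-level intensity TSV (header = array ids, first column = probe_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: intensity table needs a probe_id column and >=1 array")
    probe_col = df.columns[0]
    probe_ids = df[probe_col].tolist()
    array_ids = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:].copy()
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if bad.any() or body[col].isna().any():
            row = int((coerced.isna()).idxmax())
            raise FormatError(
                f"{path}: non-numeric or missing value at probe {probe_ids[row]!r}, "
                f"array {col!r}"
            )
        body[col] = coerced
    return IntensityMatrix(probe_ids, array_ids, body.to_numpy(dtype=float))


def read_design(path: str | Path, genotype_a: str | None = None) -> ExperimentDesign:
    """Read an experiment design TSV (array_id, genotype, treatment, replicate)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: design file is empty") from None
    if len(df) == 0:
        raise FormatError(f"{path}: design file has no rows")
    return ExperimentDesign(df, genotype_a=genotype_a)


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a probe -> probe-set map TSV (probe_id, probeset_id, probe_index)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "probeset_id": str})
    for col in ("probe_id", "probeset_id", "probe_index"):
        if col not in df.columns:
            raise FormatError(f"{path}: probe map missing column {col!r}")
    entries = [
        ProbeMapEntry(str(r.probe_id), str(r.probeset_id), int(r.probe_index))
        for r in df.itertuples(index=False)
    ]
    return ProbeMap(entries)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence map, upper-cased."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features from GFF3 (1-based inclusive on disk)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 > end1 or start1 < 1:
                raise FormatError(
                    f"{path}:{lineno}: invalid gene interval {start1}..{end1}"
                )
            gene_id = _gff3_attributes(attrs).get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks ID attribute")
            genes.append(GeneModel(gene_id, chrom, start1 - 1, end1, strand))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\telpcip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_indels(path: str | Path) -> list[IndelInterval]:
    """Read an InDel TSV (chrom, start, end, kind; 1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "kind": str})
    for col in ("chrom", "start", "end", "kind"):
        if col not in df.columns:
            raise FormatError(f"{path}: indel table missing column {col!r}")
    out = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        start1, end1 = int(r.start), int(r.end)
        if start1 > end1 or start1 < 1:
            raise FormatError(f"{path}: line {i}: invalid indel interval {start1}..{end1}")
        out.append(IndelInterval(str(r.chrom), start1 - 1, end1, str(r.kind)))
    return out


def write_indels(indels: Iterable[IndelInterval], path: str | Path) -> None:
    rows = [
        {"chrom": v.chrom, "start": v.start + 1, "end": v.end, "kind": v.kind}
        for v in indels
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a GAF-like category annotation TSV (item_id, category_id, aspect)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("item_id", "category_id", "aspect"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation table missing column {col!r}")
    bad = ~df["aspect"].isin(("BP", "MF", "CC"))
    if bad.any():
        raise FormatError(
            f"{path}: aspect must be BP/MF/CC, got {df.loc[bad, 'aspect'].iloc[0]!r}"
        )
    if df.duplicated(["item_id", "category_id", "aspect"]).any():
        dup = df[df.duplicated(["item_id", "category_id", "aspect"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate annotation ({dup.item_id}, {dup.category_id}, {dup.aspect})"
        )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with '#'-prefixed header metadata lines."""
    buf = _io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
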