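"""Readers and writers for the formats the analysis touches.

One coordinate convention is used internally: 0-based half-open intervals
(BED-native).  GTF is 1-based inclusive and is converted at this boundary
only (subtract 1 from start); gene models keep their GTF coordinates as
read plus 0-based accessors, so both conventions are explicit at the call
site and never mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "processed_transcript": "processed_transcript",
}


@dataclass(frozen=True)
class GenomeScaffold:
    id: str
    sequence: str  # upper-case, over {A,C,G,T,N}

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A coding or noncoding gene.

    ``start``/``end`` are 1-based inclusive (GTF convention); ``tss``/``tes``
    follow the same convention and are strand-aware (tss = start on '+',
    end on '-').  ``start0``/``end0``/``tss0`` give the 0-based half-open
    view used by all interval arithmetic.
    """

    gene_id: str
    scaffold: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    biotype: str  # coding | lncRNA | processed_transcript | other_nc
    known_scaffold: bool = True

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def tss0(self) -> int:
        """0-based coordinate of the TSS base."""
        return self.start - 1 if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    def window0(self, flank: int, scaffold_len: int | None = None) -> tuple[int, int]:
        """Gene body extended by ``flank`` on both sides, 0-based half-open,
        clipped at scaffold bounds (strand-agnostic by design)."""
        lo = max(0, self.start0 - flank)
        hi = self.end0 + flank
        if scaffold_len is not None:
            hi = min(hi, scaffold_len)
        return lo, hi


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with an optional label/signal."""

    scaffold: str
    start: int
    end: int
    label: str = ""
    value: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.scaffold}:{self.start}-{self.end} is empty or negative"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylRecord:
    scaffold: str
    position: int  # 1-based bp of the CpG
    coverage: int
    meth_fraction: float

    def __post_init__(self):
        if self.coverage < 0:
            raise FormatError(f"CpG {self.scaffold}:{self.position}: negative coverage")
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise FormatError(
                f"CpG {self.scaffold}:{self.position}: meth_fraction outside [0,1]"
            )

    @property
    def pos0(self) -> int:
        return self.position - 1


def make_sample_sheet(
    assay: str,
    tp_labels: Sequence[str],
    hours: Sequence[float],
    phases: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a sample sheet (one row per sample) with validated invariants."""
    hours = list(hours)
    if any(b <= a for a, b in zip(hours, hours[1:])):
        raise ValueError("sample hours must be strictly increasing within an assay")
    if assay == "rna":
        if phases is None or len(phases) != len(tp_labels):
            raise ValueError("every RNA sample needs exactly one phase")
    df = pd.DataFrame(
        {
            "sample_id": [f"{assay}_{t}" for t in tp_labels],
            "tp_label": list(tp_labels),
            "hour": hours,
            "phase": list(phases) if phases is not None else [""] * len(tp_labels),
            "assay": assay,
        }
    )
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeScaffold]:
    """Read a FASTA file into scaffolds (upper-cased, RNA U mapped to T)."""
    scaffolds: list[GenomeScaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) == 0:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        scaffolds.append(GenomeScaffold(rec.id, seq))
    if not scaffolds:
        raise FormatError(f"no FASTA records in {path}")
    return scaffolds


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path, known_scaffolds: set[str] | None = None) -> list[GeneModel]:
    """Read gene lines of a GTF into gene models (1-based inclusive spans).

    Records on scaffolds not in ``known_scaffolds`` are kept and flagged via
    ``known_scaffold=False``.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            scaf, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature != "gene":
                continue
            a = _gtf_attributes(attrs)
            if "gene_id" not in a:
                raise FormatError(f"{path}:{lineno}: gene line without gene_id")
            gid = a["gene_id"]
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            raw_bt = a.get("gene_biotype", a.get("biotype", "other_nc"))
            biotype = _BIOTYPE_MAP.get(raw_bt, "other_nc")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold=scaf,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                    biotype=biotype,
                    known_scaffold=(known_scaffolds is None or scaf in known_scaffolds),
                )
            )
    return genes


def read_bed_intervals(path: str | Path, labeled: bool = False) -> list[Interval]:
    """Read BED3+ intervals (0-based half-open), sorted by (scaffold, start).

    Column 4 is the label when ``labeled``; column 5, when present and
    numeric, is parsed as a signal value.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            scaf, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = parts[3] if labeled and len(parts) > 3 else ""
            value = None
            if len(parts) > 4:
                try:
                    value = float(parts[4])
                except ValueError:
                    value = None
            out.append(Interval(scaf, start, end, label, value))
    out.sort(key=lambda iv: (iv.scaffold, iv.start, iv.end))
    return out


def validate_segmentation(intervals: Sequence[Interval], scaffold_lengths: dict[str, int] | None = None) -> None:
    """A segmentation must tile scaffolds without gaps or overlaps."""
    by_scaf: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_scaf.setdefault(iv.scaffold, []).append(iv)
    for scaf, ivs in by_scaf.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start != a.end:
                kind = "overlap" if b.start < a.end else "gap"
                raise FormatError(
                    f"segmentation {kind} on {scaf} at {a.end}..{b.start}"
                )
        if scaffold_lengths is not None:
            if ivs[0].start != 0 or ivs[-1].end != scaffold_lengths[scaf]:
                raise FormatError(f"segmentation does not cover scaffold {scaf}")


def read_table(path: str | Path, kind: str):
    """Read a TSV with header.

    kind='counts'      -> DataFrame genes x samples of nonnegative ints
    kind='signal'      -> DataFrame genes x samples of floats
    kind='methylation' -> list[MethylRecord]
    """
    if kind == "counts":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
            raise FormatError(f"{path}: counts must be nonnegative numbers")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError(f"{path}: counts must be integers")
        return df.astype(np.int64)
    if kind == "signal":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.astype(float)
    if kind == "methylation":
        df = pd.read_csv(path, sep="\t")
        required = {"scaffold", "position", "coverage", "meth_fraction"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: missing methylation columns")
        return [
            MethylRecord(r.scaffold, int(r.position), int(r.coverage), float(r.meth_fraction))
            for r in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown table kind {kind!r}")


# ---------------------------------------------------------------------------
# writers (exact inverses of the readers, used by the simulator)
# ---------------------------------------------------------------------------

def write_fasta(scaffolds: Iterable[GenomeScaffold], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in scaffolds:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


_BIOTYPE_OUT = {
    "coding": "protein_coding",
    "lncRNA": "lncRNA",
    "processed_transcript": "processed_transcript",
    "other_nc": "other_nc",
}


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{_BIOTYPE_OUT[g.biotype]}";'
            fh.write(
                f"{g.scaffold}\tbatchreg\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.scaffold, str(iv.start), str(iv.end)]
            if iv.label or iv.value is not None:
                cols.append(iv.label)
            if iv.value is not None:
                cols.append(repr(iv.value))
            fh.write("\t".join(cols) + "\n")


def write_methylation(records: Iterable[MethylRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\tcoverage\tmeth_fraction\n")
        for r in records:
            fh.write(f"{r.scaffold}\t{r.position}\t{r.coverage}\t{r.meth_fraction:.6f}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets in GMT format (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs name, description, members")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "-"] + sorted(sets[name])) + "\n")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_signal(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")
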