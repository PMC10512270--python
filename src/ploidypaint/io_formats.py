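"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are held internally in 0-based half-open
coordinates; conversion to/from 1-based conventions (VCF, GFF3) happens
only at the I/O edge.  Variant sites are stored with their 0-based
position in the ``pos0`` column.

The variant reader accepts two allele-depth dialects:

* a sample-level ``AD`` field holding the (ref, alt) depth pair, as
  emitted by GATK-style callers and by this package's own writer;
* the VarScan dialect with separate ``RD`` (reference depth) and ``AD``
  (alternative depth) scalar fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["contig", "pos0", "ref", "alt", "ref_depth", "alt_depth"]

_NUCLEOTIDES = frozenset("ACGTacgt")


class FormatError(ValueError):
    """A file violates the expectations of its declared format."""


@dataclass
class SiteCountTable:
    """Per-site biallelic read counts: the substrate of allele-frequency work.

    Wraps a :class:`pandas.DataFrame` with columns ``contig``, ``pos0``
    (0-based), ``ref``, ``alt``, ``ref_depth``, ``alt_depth``.  Positions
    are strictly increasing within each contig and depths are
    non-negative; both are enforced at construction.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if len(df):
            if (df["ref_depth"] < 0).any() or (df["alt_depth"] < 0).any():
                raise ValueError("negative read depth in site table")
            for contig, sub in df.groupby("contig", sort=False):
                pos = sub["pos0"].to_numpy()
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(
                        f"positions not strictly increasing on contig {contig!r}"
                    )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_depth(self) -> np.ndarray:
        return (self.df["ref_depth"] + self.df["alt_depth"]).to_numpy()

    @property
    def alt_fraction(self) -> np.ndarray:
        """Alternative-allele read fraction per site; NaN at zero depth."""
        tot = self.total_depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.df["alt_depth"].to_numpy() / tot, np.nan)

    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.df["contig"]))


@dataclass
class RepeatTrack:
    """Repeat-annotation intervals in 0-based half-open coordinates.

    Overlapping or touching intervals are merged on construction, so
    membership queries can binary-search a sorted, disjoint set.
    """

    intervals: pd.DataFrame  # columns: contig, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        for c in ("contig", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"repeat track missing column {c!r}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("repeat interval with start >= end")
        merged = []
        for contig, sub in df.sort_values(["contig", "start"]).groupby(
            "contig", sort=True
        ):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # touching intervals merge too
                    cur_e = max(cur_e, e)
                else:
                    merged.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append((contig, cur_s, cur_e))
        self.intervals = pd.DataFrame(merged, columns=["contig", "start", "end"])
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, sub in self.intervals.groupby("contig", sort=False):
            self._starts[contig] = sub["start"].to_numpy()
            self._ends[contig] = sub["end"].to_numpy()

    @classmethod
    def empty(cls) -> "RepeatTrack":
        return cls(pd.DataFrame(columns=["contig", "start", "end"]))

    def covers(self, contig: str, pos0: np.ndarray | Sequence[int]) -> np.ndarray:
        """Boolean mask: does each 0-based position fall in a repeat?"""
        pos0 = np.asarray(pos0)
        starts = self._starts.get(contig)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < self._ends[contig][idx[ok]]
        return out

    def overlaps_interval(self, contig: str, start: int, end: int) -> bool:
        """True if [start, end) shares at least one base with a repeat."""
        starts = self._starts.get(contig)
        if starts is None or len(starts) == 0:
            return False
        idx = np.searchsorted(starts, end, side="left")
        return bool(idx > 0 and self._ends[contig][idx - 1] > start)


@dataclass
class ContigIndex:
    """Mapping from contig id to its length in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {n}")

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def items(self):
        return self.lengths.items()


@dataclass
class MatingTypeCounts:
    """Mating-type survey counts for one region x species cell.

    ``n_both`` counts thalli from which both idiomorphs amplified; these
    are tracked separately from the single-idiomorph counts.
    """

    region: str
    species: str
    n_mat11: int
    n_mat12: int
    n_both: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mat11, self.n_mat12, self.n_both) < 0:
            raise ValueError("mating-type counts must be non-negative")


# ---------------------------------------------------------------------------
# variant sites
# ---------------------------------------------------------------------------


def read_variant_sites(path: str | Path, sample_id: str | None = None) -> SiteCountTable:
    """Load biallelic SNP read counts from a VCF.

    Records with more than one alternative allele, symbolic or non-SNP
    alleles are dropped (the number dropped is logged).  Allele depths
    come from a paired sample-level ``AD`` field, or from the VarScan
    ``RD``/``AD`` scalar dialect.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    sample_id
        Sample to read; defaults to the only/first sample.

    Raises
    ------
    FormatError
        If no allele-depth information is present for a retained record.
    """
    rows = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        if sample_id is None:
            sample_id = samples[0]
        elif sample_id not in samples:
            raise FormatError(f"{path}: sample {sample_id!r} not in VCF")
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or rec.ref not in _NUCLEOTIDES
                or len(alts[0]) != 1
                or alts[0] not in _NUCLEOTIDES
            ):
                n_dropped += 1
                continue
            call = rec.samples[sample_id]
            ref_d, alt_d = _allele_depths(call, rec, path)
            rows.append((rec.chrom, rec.start, rec.ref, alts[0], ref_d, alt_d))
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic/non-SNP records", path, n_dropped)
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return SiteCountTable(df)


def _allele_depths(call, rec, path) -> tuple[int, int]:
    ad = call.get("AD")
    if ad is not None and not isinstance(ad, int) and len(ad) >= 2 and ad[0] is not None:
        return int(ad[0]), int(ad[1])
    # VarScan dialect: scalar RD (ref) and AD (alt)
    rd = call.get("RD")
    if rd is not None:
        if isinstance(ad, tuple):
            ad = ad[0]
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.chrom}:{rec.pos} has RD but no AD"
            )
        return int(rd), int(ad)
    raise FormatError(
        f"{path}: record {rec.chrom}:{rec.pos} carries no allele-depth field"
    )


def write_variant_sites(
    table: SiteCountTable,
    path: str | Path,
    sample_id: str = "sample",
    contigs: ContigIndex | None = None,
) -> None:
    """Write a site table as a minimal VCF 4.2 with a paired AD field."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs is not None:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in table.contigs():
            lines.append(f"##contig=<ID={name}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for row in table.df.itertuples(index=False):
        lines.append(
            f"{row.contig}\t{row.pos0 + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
            f"AD\t{row.ref_depth},{row.alt_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# intervals, indices, alignments, survey tables
# ---------------------------------------------------------------------------


def read_repeat_intervals(path: str | Path) -> RepeatTrack:
    """Read repeat intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive); both are normalised to 0-based half-open internally.  The
    format is chosen by file extension (``.gff``/``.gff3`` vs BED
    otherwise)."""
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            if is_gff:
                contig, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
            else:
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed interval line") from exc
        rows.append((contig, start, end))
    return RepeatTrack(pd.DataFrame(rows, columns=["contig", "start", "end"]))


def write_bed(track: RepeatTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_contig_index(path: str | Path) -> ContigIndex:
    """Read contig lengths from a FASTA-index-style TSV (name, length, ...)."""
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            lengths[parts[0]] = int(parts[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed index line") from exc
    return ContigIndex(lengths)


def write_contig_index(contigs: ContigIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in contigs.items():
            fh.write(f"{name}\t{length}\n")


def read_alignment(path: str | Path) -> tuple[str, str]:
    """Read a pairwise-aligned FASTA; returns the two gapped sequences.

    Raises :class:`FormatError` unless the file holds exactly two records
    of equal aligned length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(f"{path}: expected exactly 2 aligned sequences, got {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise FormatError(
            f"{path}: aligned sequences differ in length ({len(a)} vs {len(b)})"
        )
    return a, b


def write_alignment(pair: tuple[str, str], path: str | Path,
                    names: tuple[str, str] = ("MAT1-1", "MAT1-2")) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for seq, name in zip(pair, names)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mating_table(path: str | Path) -> list[MatingTypeCounts]:
    """Read a mating-type survey TSV.

    Expected columns: ``region``, ``species``, ``mat11``, ``mat12`` and
    optionally ``both`` (thalli amplifying both idiomorphs).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"region", "species", "mat11", "mat12"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: survey table needs columns {sorted(required)}"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MatingTypeCounts(
                region=str(row.region),
                species=str(row.species),
                n_mat11=int(row.mat11),
                n_mat12=int(row.mat12),
                n_both=int(getattr(row, "both", 0) or 0),
            )
        )
    return out


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    """Write a simulator truth table as a sidecar TSV."""
    truth.to_csv(path, sep="\t", index=False)
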