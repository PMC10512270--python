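"""Ancestry painting of a hybrid metagenome against a pure-culture reference.

Each SNP's alternative allele is classified relative to the reference
genotype: sites whose "other" (alternative) allele frequency exceeds 0.2
are accepted as a true non-reference subgenome allele, sites below 0.1
are treated as sequencing errors (reference-matching, "lupina"), and the
closed interval [0.1, 0.2] is left missing to stay conservative against
paralogs.  From these calls the module builds the artificial "other"
haplotype, consensus haplotypes for haploid samples, windowed median
allele-frequency tracks, and loss-of-heterozygosity (LOH) tract calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ContigIndex, RepeatTrack, SiteCountTable
from .ploidy_maf import MAFHistogram, unfolded_histogram

logger = logging.getLogger(__name__)

CALL_OTHER = "other"
CALL_LUPINA = "lupina"
CALL_MISSING = "missing"

OTHER_MIN_FREQ = 0.2   # frequency must exceed this to call "other"
ERROR_MAX_FREQ = 0.1   # frequency below this is a sequencing error


@dataclass
class AncestryCallTable:
    """Per-site ancestry calls with the "other" allele read frequency.

    Columns: ``contig``, ``pos0``, ``ref``, ``alt``, ``other_freq``,
    ``call`` (one of ``other`` / ``lupina`` / ``missing``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"contig", "pos0", "ref", "alt", "other_freq", "call"}
        missing = needed - set(self.df.columns)
        if missing:
            raise ValueError(f"ancestry call table missing columns: {sorted(missing)}")
        bad = ~self.df["call"].isin([CALL_OTHER, CALL_LUPINA, CALL_MISSING])
        if bad.any():
            raise ValueError("invalid ancestry call label")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class HaplotypeMatrix:
    """Haplotype-by-site allele matrix over the shared variable sites.

    ``alleles`` holds one row per haplotype (the artificial "other"
    haplotype, the reference-matching haplotype and one consensus per
    haploid sample) and one column per retained site; cells are base
    symbols or NaN.  ``sites`` carries the per-column coordinates.  Only
    columns genotyped in every *sample* consensus are retained; the
    artificial "other" haplotype may still be missing within a column.
    """

    alleles: pd.DataFrame
    sites: pd.DataFrame  # columns: contig, pos0, ref, alt

    def __post_init__(self) -> None:
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError("allele matrix and site frame disagree on column count")

    @property
    def labels(self) -> list[str]:
        return list(self.alleles.index)

    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class MedianTrack:
    """Non-overlapping windowed medians of the "other" allele frequency.

    Columns: ``contig``, ``start``, ``end`` (0-based half-open),
    ``n_sites``, ``median`` (NaN = missing), ``partial`` (trailing
    window shorter than the nominal length).
    """

    df: pd.DataFrame
    window_bp: int


def classify_alleles(
    sample: SiteCountTable,
    reference_calls: set[tuple[str, int]] | None = None,
) -> AncestryCallTable:
    """Classify each site's alternative allele against the reference.

    ``reference_calls``, when given, is the set of ``(contig, pos0)``
    coordinates at which the reference (pure-culture) genotype is
    confidently known; sites outside it are set to missing (their count
    is logged).  The frequency thresholds partition [0, 1] exhaustively:
    > 0.2 is "other", < 0.1 is "lupina", the closed middle is missing.
    """
    df = sample.df.copy()
    tot = sample.total_depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, df["alt_depth"].to_numpy() / tot, np.nan)
    call = np.full(len(df), CALL_MISSING, dtype=object)
    with np.errstate(invalid="ignore"):
        call[freq > OTHER_MIN_FREQ] = CALL_OTHER
        call[freq < ERROR_MAX_FREQ] = CALL_LUPINA
    if reference_calls is not None:
        known = np.array(
            [(c, p) in reference_calls for c, p in zip(df["contig"], df["pos0"])]
        )
        n_unknown = int((~known).sum())
        if n_unknown:
            logger.info("%d sites absent from reference calls set to missing", n_unknown)
        call[~known] = CALL_MISSING
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos0": df["pos0"],
            "ref": df["ref"],
            "alt": df["alt"],
            "other_freq": freq,
            "call": call,
        }
    )
    return AncestryCallTable(out)


def unfolded_af(calls: AncestryCallTable, bin_width: float = 0.02) -> MAFHistogram:
    """Unit-area unfolded distribution of the "other" allele frequency
    over classified (non-missing) sites; on a balanced triploid hybrid
    this is bimodal at 1/3 and 2/3."""
    sel = calls.df["call"] != CALL_MISSING
    return unfolded_histogram(calls.df.loc[sel, "other_freq"].to_numpy(), bin_width)


def build_haplotype_matrix(
    calls: AncestryCallTable,
    haploids: dict[str, SiteCountTable],
    haploid_maf_cutoff: float = 0.05,
    other_label: str = "other",
    reference_label: str = "lupina",
) -> HaplotypeMatrix:
    """Assemble the haplotype matrix used for window genealogies.

    The artificial ``other`` haplotype carries the alternative allele
    where the ancestry call is "other", the reference allele where it is
    "lupina", and is missing elsewhere.  The ``lupina`` row is the
    reference-matching haplotype (the reference allele at every site).
    Each haploid sample contributes its majority allele, masked to
    missing when its minor allele frequency reaches
    ``haploid_maf_cutoff`` or the site is absent.  Columns not genotyped
    in every haploid consensus are dropped; the "other" haplotype's own
    missing cells are retained.
    """
    if len(haploids) + 2 < 4:
        raise ValueError("need at least 4 haplotypes for window genealogies")
    sites = calls.df[["contig", "pos0", "ref", "alt"]].reset_index(drop=True)
    n = len(sites)
    other = np.where(
        calls.df["call"] == CALL_OTHER,
        calls.df["alt"],
        np.where(calls.df["call"] == CALL_LUPINA, calls.df["ref"], None),
    )
    rows: dict[str, np.ndarray] = {
        other_label: other,
        reference_label: sites["ref"].to_numpy(dtype=object),
    }
    key = pd.MultiIndex.from_frame(sites[["contig", "pos0"]])
    for name, table in haploids.items():
        if name in rows:
            raise ValueError(f"duplicate haplotype label {name!r}")
        t = table.df.set_index(["contig", "pos0"])
        t = t[~t.index.duplicated()]
        aligned = t.reindex(key)
        ref_d = aligned["ref_depth"].to_numpy(dtype=float)
        alt_d = aligned["alt_depth"].to_numpy(dtype=float)
        tot = ref_d + alt_d
        with np.errstate(invalid="ignore", divide="ignore"):
            minor = np.minimum(ref_d, alt_d) / tot
        consensus = np.where(alt_d > ref_d, aligned["alt"], aligned["ref"]).astype(object)
        bad = ~np.isfinite(minor) | (minor >= haploid_maf_cutoff) | (tot == 0)
        consensus[bad] = None
        rows[name] = consensus
    alleles = pd.DataFrame(
        {i: {lab: rows[lab][i] for lab in rows} for i in range(n)}
    ).reindex(list(rows))
    # completeness across samples: every row except the artificial
    # "other" haplotype must be genotyped
    sample_rows = [lab for lab in rows if lab != other_label]
    complete = alleles.loc[sample_rows].notna().all(axis=0).to_numpy()
    alleles = alleles.loc[:, complete]
    alleles.columns = range(int(complete.sum()))
    sites = sites.loc[complete].reset_index(drop=True)
    return HaplotypeMatrix(alleles=alleles, sites=sites)


def windowed_median(
    calls: AncestryCallTable,
    window_bp: int = 7_500,
    repeats: RepeatTrack | None = None,
    contigs: ContigIndex | None = None,
) -> MedianTrack:
    """Median "other" allele frequency in non-overlapping windows.

    Windows tile each contig from coordinate 0.  The median is taken
    over classified (non-missing) sites; windows with no usable site or
    any overlap with a repeat interval are missing.  A trailing window
    shorter than ``window_bp`` is kept and flagged ``partial``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = calls.df
    rows = []
    contig_names = (
        list(contigs.lengths) if contigs is not None else list(dict.fromkeys(df["contig"]))
    )
    for contig in contig_names:
        sub = df[df["contig"] == contig]
        length = (
            contigs[contig]
            if contigs is not None
            else (int(sub["pos0"].max()) + 1 if len(sub) else 0)
        )
        if length == 0:
            continue
        pos = sub["pos0"].to_numpy()
        freq = sub["other_freq"].to_numpy()
        usable = (sub["call"] != CALL_MISSING).to_numpy()
        if repeats is not None and len(sub):
            usable &= ~repeats.covers(contig, pos)
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            in_win = usable & (pos >= start) & (pos < end)
            n_sites = int(in_win.sum())
            masked = repeats is not None and repeats.overlaps_interval(
                contig, start, end
            )
            med = np.nan if (masked or n_sites == 0) else float(np.median(freq[in_win]))
            rows.append((contig, start, end, n_sites, med, end - start < window_bp))
    out = pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_sites", "median", "partial"]
    )
    return MedianTrack(df=out, window_bp=window_bp)


def detect_loh_tracts(
    track: MedianTrack,
    low_cut: float = 0.1,
    high_cut: float = 0.9,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Call loss-of-heterozygosity tracts from a median track.

    A tract is a maximal run of at least ``min_windows`` consecutive
    non-missing windows whose median lies below ``low_cut`` (direction
    ``lupina``: the reference allele took over) or above ``high_cut``
    (direction ``other``).  Missing windows break runs.  Returns a
    DataFrame with columns ``contig``, ``start``, ``end``,
    ``direction``, ``n_windows``.
    """
    if min_windows < 1:
        raise ValueError("min_windows must be >= 1")
    rows = []
    for contig, sub in track.df.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        run_state: str | None = None
        run: list[tuple[int, int]] = []

        def close() -> None:
            nonlocal run, run_state
            if run_state is not None and len(run) >= min_windows:
                rows.append((contig, run[0][0], run[-1][1], run_state, len(run)))
            run, run_state = [], None

        for w in sub.itertuples(index=False):
            if not np.isfinite(w.median):
                state = None
            elif w.median < low_cut:
                state = "lupina"
            elif w.median > high_cut:
                state = "other"
            else:
                state = None
            if state != run_state:
                close()
                run_state = state
            if state is not None:
                run.append((w.start, w.end))
        close()
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "direction", "n_windows"]
    )
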