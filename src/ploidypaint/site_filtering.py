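"""SNP quality filters producing the analysis-ready site set.

The filters mirror the variant-hygiene steps typical of read-count
ploidy work on metagenome-derived callsets: keep biallelic SNPs on long
contigs, genotyped in every sample of the run set, outside annotated
repeats, and inside a total-depth window.  "Above 300x or below 50x" is
read literally: a site at exactly 50x or exactly 300x survives.

Filters are applied in a fixed order (biallelic, contig length,
completeness, repeat overlap, coverage) and a removal ledger reports how
many distinct sites each step removed.  The surviving set is independent
of the order; only the ledger attribution depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ContigIndex, RepeatTrack, SiteCountTable

FILTER_ORDER = ["biallelic", "contig_length", "completeness", "repeats", "coverage"]


@dataclass(frozen=True)
class FilterConfig:
    min_contig_len: int = 100_000
    min_depth: int = 50       # inclusive lower bound
    max_depth: int = 300      # inclusive upper bound
    require_biallelic: bool = True
    require_complete: bool = True
    exclude_repeats: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.max_depth <= 0:
            raise ValueError("coverage bounds must be positive")
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be below max_depth")
        if self.min_contig_len < 0:
            raise ValueError("min_contig_len must be non-negative")


def filter_sites(
    tables: dict[str, SiteCountTable],
    repeats: RepeatTrack | None,
    contigs: ContigIndex,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[dict[str, SiteCountTable], pd.DataFrame]:
    """Apply the quality filters to a set of per-sample site tables.

    Parameters
    ----------
    tables
        One :class:`SiteCountTable` per sample, sharing the contig
        namespace of ``contigs``.
    repeats
        Repeat annotation; ignored when ``cfg.exclude_repeats`` is off.
    contigs
        Contig lengths; every contig referenced by a table must exist.

    Returns
    -------
    (filtered_tables, ledger)
        Tables restricted to the surviving sites, and a ledger
        DataFrame (``filter``, ``n_removed``) in application order.
    """
    if not tables:
        raise ValueError("no sample tables given")
    for name, t in tables.items():
        for contig in t.contigs():
            if contig not in contigs:
                raise ValueError(
                    f"sample {name!r} references contig {contig!r} absent from index"
                )

    # per-sample site frames keyed by (contig, pos0)
    frames = {
        name: t.df.set_index(["contig", "pos0"], drop=False) for name, t in tables.items()
    }
    union = pd.Index([])
    for f in frames.values():
        union = union.union(f.index)
    alive = pd.Series(True, index=union)
    removed: dict[str, int] = {}

    # biallelic: the table type already enforces one ALT per record;
    # sites represented more than once in a sample (a multi-allelic site
    # split across records) are removed here
    n0 = int(alive.sum())
    if cfg.require_biallelic:
        for f in frames.values():
            dup = f.index[f.index.duplicated(keep=False)].unique()
            alive.loc[alive.index.isin(dup)] = False
    removed["biallelic"] = n0 - int(alive.sum())

    n0 = int(alive.sum())
    short = {c for c, n in contigs.items() if n < cfg.min_contig_len}
    if short:
        mask = alive.index.get_level_values(0).isin(short)
        alive.loc[mask] = False
    removed["contig_length"] = n0 - int(alive.sum())

    n0 = int(alive.sum())
    if cfg.require_complete:
        present = None
        for f in frames.values():
            idx = f.index.unique()
            present = idx if present is None else present.intersection(idx)
        alive.loc[~alive.index.isin(present)] = False
    removed["completeness"] = n0 - int(alive.sum())

    n0 = int(alive.sum())
    if cfg.exclude_repeats and repeats is not None:
        contigs_seen = alive.index.get_level_values(0)
        pos_seen = alive.index.get_level_values(1)
        mask = np.zeros(len(alive), dtype=bool)
        for contig in pd.unique(contigs_seen):
            sel = contigs_seen == contig
            mask[sel] = repeats.covers(contig, pos_seen[sel].to_numpy())
        alive.loc[mask] = False
    removed["repeats"] = n0 - int(alive.sum())

    n0 = int(alive.sum())
    for f in frames.values():
        depth = f["ref_depth"] + f["alt_depth"]
        bad = f.index[(depth < cfg.min_depth) | (depth > cfg.max_depth)]
        alive.loc[alive.index.isin(bad)] = False
    removed["coverage"] = n0 - int(alive.sum())

    surviving = alive.index[alive]
    out = {}
    for name, f in frames.items():
        keep = f.loc[f.index.isin(surviving)].reset_index(drop=True)
        out[name] = SiteCountTable(keep)
    ledger = pd.DataFrame(
        {"filter": FILTER_ORDER, "n_removed": [removed[k] for k in FILTER_ORDER]}
    )
    return out, ledger
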