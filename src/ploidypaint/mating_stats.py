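"""Mating-type ratio tests and idiomorph copy-ratio estimation.

Heterothallic fungi need both mating types (MAT1-1, MAT1-2) locally for
sexual reproduction, and regular sex keeps their frequencies near 1:1.
Each region x species survey cell is tested against that expectation
with a two-sided exact binomial test; thalli from which both idiomorphs
amplified are reported separately and excluded from the test's n.

The copy-ratio estimator divides the mean repeat-masked read depth in a
target interval (e.g. the MAT1-1 idiomorph of a triploid hybrid) by the
genome-wide repeat-masked mean; a region carried on two of three
chromosome sets sits near 2/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import MatingTypeCounts, RepeatTrack, SiteCountTable

logger = logging.getLogger(__name__)


@dataclass
class RatioTestResult:
    region: str
    species: str
    n: int
    n_mat11: int
    n_mat12: int
    n_both_excluded: int
    p_value: float
    p_display: str
    monomorphic: bool


@dataclass
class CopyRatioEstimate:
    contig: str
    start: int
    end: int
    mean_depth_region: float
    mean_depth_genome: float

    @property
    def ratio(self) -> float:
        return self.mean_depth_region / self.mean_depth_genome


def exact_binomial_p(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k successes in n trials.

    Uses the minimum-likelihood two-sided convention; for the symmetric
    null p0 = 0.5 this equals the doubled smaller tail capped at 1, so
    the most balanced split of an odd n gives exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def format_p(p: float) -> str:
    """Display rounding for p-values: one decimal when >= 0.095,
    otherwise two significant figures in scientific notation."""
    if p >= 0.095:
        s = f"{p:.1f}"
        return s.rstrip("0").rstrip(".") if "." in s else s
    return f"{p:.1e}"


def ratio_report(
    counts: list[MatingTypeCounts], p0: float = 0.5
) -> list[RatioTestResult]:
    """One exact 1:1 test per region x species survey cell.

    Thalli amplifying both idiomorphs are counted in
    ``n_both_excluded`` and removed from the binomial n.  Cells with
    n = 0 are skipped (logged).  Cells where one mating type is absent
    are flagged ``monomorphic``.
    """
    out = []
    for c in counts:
        n = c.n_mat11 + c.n_mat12
        if n == 0:
            logger.info("skipping %s/%s: no single-idiomorph thalli", c.region, c.species)
            continue
        p = exact_binomial_p(c.n_mat11, n, p0)
        out.append(
            RatioTestResult(
                region=c.region,
                species=c.species,
                n=n,
                n_mat11=c.n_mat11,
                n_mat12=c.n_mat12,
                n_both_excluded=c.n_both,
                p_value=p,
                p_display=format_p(p),
                monomorphic=(min(c.n_mat11, c.n_mat12) == 0),
            )
        )
    return out


def copy_ratio(
    sample: SiteCountTable,
    region: tuple[str, int, int],
    repeats: RepeatTrack | None = None,
) -> CopyRatioEstimate:
    """Mean depth in a region relative to the genome-wide mean.

    Depth is total (ref + alt) read depth at each site; sites inside
    repeat intervals are excluded from both means.  Raises if the region
    holds no usable site after masking.
    """
    contig, start, end = region
    if end <= start:
        raise ValueError("empty region")
    df = sample.df
    usable = np.ones(len(df), dtype=bool)
    if repeats is not None:
        for c in dict.fromkeys(df["contig"]):
            sel = (df["contig"] == c).to_numpy()
            usable[sel] = ~repeats.covers(c, df.loc[sel, "pos0"].to_numpy())
    depth = sample.total_depth.astype(float)
    in_region = (
        (df["contig"] == contig).to_numpy()
        & (df["pos0"].to_numpy() >= start)
        & (df["pos0"].to_numpy() < end)
        & usable
    )
    if not in_region.any():
        raise ValueError("region holds no usable site after repeat masking")
    if not usable.any():
        raise ValueError("no usable sites genome-wide after repeat masking")
    return CopyRatioEstimate(
        contig=contig,
        start=start,
        end=end,
        mean_depth_region=float(depth[in_region].mean()),
        mean_depth_genome=float(depth[usable].mean()),
    )
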