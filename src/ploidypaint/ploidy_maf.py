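"""Folded minor-allele-frequency spectra and template-based ploidy calls.

The minor-allele frequency (MAF) of a biallelic site is the read-count
proportion of the less frequent allele, so folded spectra live on
[0, 0.5].  A diploid's heterozygous sites pile up near 0.5, a triploid's
near 1/3, a tetraploid's near 1/4 and 1/2, while a haploid shows only
the exponential decay of sequencing errors near 0.  "Ploidy" is meant in
the broad sense that includes heterokaryons: an n + n + n thallus with
balanced nuclei is read-count-indistinguishable from a true triploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SiteCountTable

#: folded-mode templates per ploidy class
PLOIDY_TEMPLATES: dict[str, tuple[float, ...]] = {
    "diploid": (0.5,),
    "triploid": (1 / 3,),
    "tetraploid": (0.25, 0.5),
}


@dataclass
class MAFHistogram:
    """A unit-area allele-frequency histogram.

    Folded spectra span [0, 0.5]; the same container serves unfolded
    spectra on [0, 1].  ``density`` integrates to 1 over the bins unless
    the histogram is empty (``n_sites == 0``), in which case it is all
    zeros and ``is_empty`` is set.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_sites: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0

    def mass(self, lo: float = -np.inf, hi: float = np.inf) -> float:
        """Probability mass of bins whose centers lie in [lo, hi]."""
        sel = (self.bin_centers >= lo) & (self.bin_centers <= hi)
        return float(np.sum(self.density[sel]) * self.bin_width)


@dataclass
class PloidyCall:
    label: str  # haploid | diploid | triploid | tetraploid | ambiguous
    modes: list[float] = field(default_factory=list)
    mass_above_cutoff: float = 0.0


def folded_maf(table: SiteCountTable, bin_width: float = 0.02) -> MAFHistogram:
    """Build the folded MAF spectrum of a (filtered) site table.

    MAF per site is ``min(alt, ref) / (alt + ref)``; sites with MAF = 0
    (and zero-depth sites) are excluded, and the remaining histogram is
    scaled to unit area.  An input left empty after the exclusion gives
    an empty (all-zero) histogram rather than an error.
    """
    if not 0 < bin_width <= 0.5:
        raise ValueError("bin_width must lie in (0, 0.5]")
    edges = np.arange(0, 0.5 + bin_width / 2, bin_width)
    if edges[-1] < 0.5:
        edges = np.append(edges, 0.5)
    tot = table.total_depth.astype(float)
    alt = table.df["alt_depth"].to_numpy(dtype=float) if len(table) else np.array([])
    ref = table.df["ref_depth"].to_numpy(dtype=float) if len(table) else np.array([])
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, np.minimum(alt, ref) / tot, np.nan)
    maf = maf[np.isfinite(maf) & (maf > 0)]
    if maf.size == 0:
        return MAFHistogram(edges, np.zeros(len(edges) - 1), 0)
    counts, _ = np.histogram(maf, bins=edges)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    return MAFHistogram(edges, density, int(maf.size))


def unfolded_histogram(freqs: np.ndarray, bin_width: float = 0.02) -> MAFHistogram:
    """Unit-area histogram of (unfolded) allele frequencies on [0, 1]."""
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    if edges[-1] < 1:
        edges = np.append(edges, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs[np.isfinite(freqs)]
    if freqs.size == 0:
        return MAFHistogram(edges, np.zeros(len(edges) - 1), 0)
    counts, _ = np.histogram(freqs, bins=edges)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    return MAFHistogram(edges, density, int(freqs.size))


def classify_ploidy(
    h: MAFHistogram,
    error_cutoff: float = 0.15,
    min_peak_mass: float = 0.2,
    mode_tolerance: float = 0.05,
    secondary_ratio: float = 0.3,
) -> PloidyCall:
    """Classify ploidy from a folded MAF spectrum by template matching.

    A sample whose spectrum carries less than ``min_peak_mass`` of its
    probability above ``error_cutoff`` shows only the sequencing-error
    decay and is called haploid.  Otherwise the maximum-density bin
    above the cutoff is matched to the template mode sets {1/3} (
    triploid), {1/2} (diploid) and {1/4, 1/2} (tetraploid) within
    ``mode_tolerance``; when the primary mode sits near 0.25 or 0.5 the
    presence of the partner tetraploid mode is decided by whether a
    local peak of at least ``secondary_ratio`` times the primary density
    exists near the partner location.  A primary mode matching no
    template is called ambiguous.  Ties between templates go to the
    lower mode.
    """
    if h.is_empty:
        return PloidyCall("haploid", [], 0.0)
    mass_above = h.mass(lo=error_cutoff)
    if mass_above < min_peak_mass:
        return PloidyCall("haploid", [], mass_above)

    centers = h.bin_centers
    above = centers >= error_cutoff
    dens = np.where(above, h.density, -np.inf)
    primary_idx = int(np.argmax(dens))
    primary = float(centers[primary_idx])
    primary_dens = float(h.density[primary_idx])

    def peak_near(loc: float) -> float:
        sel = above & (np.abs(centers - loc) <= mode_tolerance)
        return float(h.density[sel].max()) if sel.any() else 0.0

    modes = [primary]
    # candidate templates in ascending mode order: ties go to the lower mode
    if abs(primary - 0.25) <= mode_tolerance:
        partner = peak_near(0.5)
        if partner >= secondary_ratio * primary_dens:
            modes.append(0.5)
        return PloidyCall("tetraploid", modes, mass_above)
    if abs(primary - 1 / 3) <= mode_tolerance:
        return PloidyCall("triploid", modes, mass_above)
    if abs(primary - 0.5) <= mode_tolerance:
        partner = peak_near(0.25)
        if partner >= secondary_ratio * primary_dens:
            return PloidyCall("tetraploid", [0.25, primary], mass_above)
        return PloidyCall("diploid", modes, mass_above)
    return PloidyCall("ambiguous", modes, mass_above)


def plot_maf(h: MAFHistogram, ax=None, **bar_kwargs):
    """Bar plot of a MAF spectrum (lazy matplotlib import)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(h.bin_centers, h.density, width=h.bin_width, align="center", **bar_kwargs)
    ax.set_xlabel("minor allele frequency")
    ax.set_ylabel("density")
    return ax
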