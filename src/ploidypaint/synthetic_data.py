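"""Seeded generators that emulate the read-count structure of whole-thallus
(metagenomic) short-read sequencing of a lichenized fungus.

The generators produce truth-annotated inputs for every downstream stage:

* per-site biallelic read counts under haploid / diploid / triploid /
  tetraploid / heterokaryotic allele-copy configurations, with a
  negative-binomial coverage model and a symmetric sequencing-error tail;
* hybrid mosaics whose contigs tile into ancestry blocks (the "other"
  subgenome present on one or two of three chromosome sets, or lost to
  loss-of-heterozygosity in favour of either parent);
* a multi-taxon panel in which the "other" subgenome is copied from a
  designated donor lineage, for genealogy-recovery experiments;
* aligned mating-type idiomorph pairs with conserved flanks, a divergent
  core and a single-sequence indel;
* binomial mating-type samples at a given MAT1-1 proportion.

A single integer seed governs every draw within one call; identical
arguments and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MatingTypeCounts, SiteCountTable, SITE_COLUMNS

_BASES = np.array(list("ACGT"))

#: true alternative-allele fraction of each ancestry state in a triploid
#: hybrid: "other" on one of three copies, on two of three, or lost to
#: loss of heterozygosity in favour of either parent.
STATE_FRACTION: dict[str, float] = {
    "other_1of3": 1.0 / 3.0,
    "other_2of3": 2.0 / 3.0,
    "LOH_lupina": 0.0,
    "LOH_other": 1.0,
}

PLOIDY_LABELS = (
    "haploid",
    "diploid",
    "triploid",
    "tetraploid",
    "trikaryon",
    "chimera",
)


@dataclass(frozen=True)
class PloidyModel:
    """Allele-copy configuration of a nuclear state, in the broad sense
    that includes heterokaryons (n + n, n + n + n, ...): what matters for
    read counts is how many of the total allele copies carry the
    alternative allele at a heterozygous site.

    ``alt_copy_distribution`` maps "number of copies carrying the
    alternative allele" to its probability at a heterozygous site.
    Heterokaryotic and chimeric states are built from mixing proportions
    of their component genotypes; with the default balanced proportions
    they are read-count-indistinguishable from true polyploids of the
    same total copy number.
    """

    label: str
    copy_number: int
    alt_copy_distribution: Mapping[int, float]
    mixing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.label not in PLOIDY_LABELS:
            raise ValueError(f"invalid ploidy label {self.label!r}")
        if not 1 <= self.copy_number <= 4:
            raise ValueError("copy_number must be in 1..4")
        probs = np.array(list(self.alt_copy_distribution.values()), dtype=float)
        copies = np.array(list(self.alt_copy_distribution.keys()))
        if np.any(copies < 0) or np.any(copies > self.copy_number):
            raise ValueError("alt copies must lie in [0, copy_number]")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("alt-copy probabilities must sum to 1")

    # -- canonical configurations ------------------------------------------

    @classmethod
    def haploid(cls) -> "PloidyModel":
        # a single copy cannot be heterozygous: the only signal is error
        return cls("haploid", 1, {0: 1.0})

    @classmethod
    def diploid(cls) -> "PloidyModel":
        return cls("diploid", 2, {1: 1.0})

    @classmethod
    def triploid(cls) -> "PloidyModel":
        """Allotriploid-like: alternative allele on one or two of three
        copies with equal weight, matching similar contributions of the
        1/3 and 2/3 modes."""
        return cls("triploid", 3, {1: 0.5, 2: 0.5})

    @classmethod
    def tetraploid(cls) -> "PloidyModel":
        return cls("tetraploid", 4, {1: 1 / 3, 2: 1 / 3, 3: 1 / 3})

    @classmethod
    def trikaryon(cls, mixing: Sequence[float] = (1, 1, 1)) -> "PloidyModel":
        """n + n + n heterokaryon of three haploid nuclei at the given
        mixing proportions (default balanced)."""
        w = _norm_mixing(mixing, 3)
        return cls("trikaryon", 3, {1: 0.5, 2: 0.5}, mixing=w)

    @classmethod
    def chimera(cls, mixing: Sequence[float] = (2, 1)) -> "PloidyModel":
        """2n + n chimera: a diploid and a haploid component sharing the
        thallus; mixing gives (diploid, haploid) genome-copy weights."""
        w = _norm_mixing(mixing, 2)
        return cls("chimera", 3, {1: 0.5, 2: 0.5}, mixing=w)

    def sample_alt_fraction(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """True alternative-allele fractions at ``n`` heterozygous sites."""
        copies = np.array(list(self.alt_copy_distribution.keys()))
        probs = np.array(list(self.alt_copy_distribution.values()), dtype=float)
        k = rng.choice(copies, size=n, p=probs)
        if self.mixing is None:
            return k / self.copy_number
        # heterokaryon/chimera: the alt-carrying copies are a random subset
        # of the component nuclei; the realised fraction is the summed
        # weight of that subset (equal to k/copy_number when balanced)
        if self.label == "trikaryon":
            weights = np.asarray(self.mixing)
        else:  # chimera 2n+n: per-copy weights (d/2, d/2, h)
            d, h = self.mixing
            weights = np.array([d / 2, d / 2, h])
        out = np.empty(n)
        for i, ki in enumerate(k):
            idx = rng.choice(len(weights), size=int(ki), replace=False)
            out[i] = weights[idx].sum()
        return out


def _norm_mixing(mixing: Sequence[float], k: int) -> tuple[float, ...]:
    w = np.asarray(mixing, dtype=float)
    if len(w) != k or np.any(w <= 0):
        raise ValueError(f"mixing must be {k} positive weights")
    return tuple(w / w.sum())


@dataclass(frozen=True)
class CoverageModel:
    """Per-site sequencing depth: negative binomial with mean
    ``mean_depth`` and dispersion ``overdispersion`` (variance
    ``m + m^2/k``); ``overdispersion=None`` degenerates to Poisson."""

    mean_depth: float = 150.0
    overdispersion: float | None = 20.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")

    def sample(
        self, rng: np.random.Generator, n: int, mean_scale: np.ndarray | float = 1.0
    ) -> np.ndarray:
        """Sample ``n`` depths; ``mean_scale`` multiplies the mean per
        site (used for copy-dosage regions)."""
        mean = self.mean_depth * np.broadcast_to(
            np.asarray(mean_scale, dtype=float), (n,)
        )
        if self.overdispersion is None:
            return rng.poisson(mean)
        k = self.overdispersion
        return rng.negative_binomial(k, k / (k + mean))


@dataclass(frozen=True)
class ErrorModel:
    """Symmetric substitution error at rate ``rate`` per read base; an
    erroneous base is read as the opposite allele of the biallelic pair."""

    rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")

    def observed_fraction(self, true_fraction: np.ndarray | float) -> np.ndarray:
        """Per-read probability of observing the alternative allele."""
        f = np.asarray(true_fraction, dtype=float)
        return f * (1 - self.rate) + (1 - f) * self.rate


def _random_ref_alt(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def simulate_read_counts(
    ploidy: PloidyModel,
    n_sites: int,
    het_fraction: float = 1.0,
    coverage: CoverageModel = CoverageModel(),
    error: ErrorModel = ErrorModel(),
    seed: int = 0,
    contig: str = "contig_1",
    site_spacing: int = 100,
) -> SiteCountTable:
    """Simulate biallelic per-site read counts for one sample.

    A fraction ``het_fraction`` of the sites is heterozygous: the true
    alternative-allele fraction is (alt copies)/(copy number), with the
    number of alt-carrying copies drawn from the ploidy model.  The
    remaining sites are homozygous reference (true fraction 0), so their
    alternative reads come from sequencing error only.  The
    alternative-allele depth at each site is binomial in the sampled
    total depth with success probability ``f(1-eps) + (1-f)eps``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_het = int(round(n_sites * het_fraction))
    true_f = np.zeros(n_sites)
    if n_het:
        het_idx = rng.choice(n_sites, size=n_het, replace=False)
        true_f[het_idx] = ploidy.sample_alt_fraction(rng, n_het)
    depth = coverage.sample(rng, n_sites)
    alt_depth = rng.binomial(depth, error.observed_fraction(true_f))
    ref, alt = _random_ref_alt(rng, n_sites)
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos0": np.arange(n_sites) * site_spacing,
            "ref": ref,
            "alt": alt,
            "ref_depth": depth - alt_depth,
            "alt_depth": alt_depth,
        }
    )
    return SiteCountTable(df)


# ---------------------------------------------------------------------------
# hybrid mosaics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MosaicSpec:
    """Block structure of a triploid hybrid along its contigs.

    ``blocks[contig]`` is a list of ``(start, end, state)`` intervals in
    0-based half-open coordinates that tile the contig without overlap;
    states come from :data:`STATE_FRACTION`.  ``het_density`` is the
    expected number of inter-subgenome heterozygous sites per bp.
    """

    contigs: Mapping[str, int]
    blocks: Mapping[str, Sequence[tuple[int, int, str]]]
    het_density: float = 0.005

    def __post_init__(self) -> None:
        if self.het_density <= 0:
            raise ValueError("het_density must be positive")
        for contig, length in self.contigs.items():
            blocks = sorted(self.blocks.get(contig, ()), key=lambda b: b[0])
            if not blocks:
                raise ValueError(f"contig {contig!r} has no blocks")
            cursor = 0
            for start, end, state in blocks:
                if state not in STATE_FRACTION:
                    raise ValueError(f"unknown ancestry state {state!r}")
                if start != cursor:
                    raise ValueError(
                        f"blocks do not tile contig {contig!r}: gap/overlap at {start}"
                    )
                if end <= start:
                    raise ValueError(f"empty block on contig {contig!r}")
                cursor = end
            if cursor != length:
                raise ValueError(
                    f"blocks do not cover contig {contig!r} (end {cursor} != {length})"
                )

    @classmethod
    def random(
        cls,
        contigs: Mapping[str, int],
        mean_block_bp: float = 40_000,
        state_probs: Mapping[str, float] | None = None,
        het_density: float = 0.005,
        seed: int = 0,
    ) -> "MosaicSpec":
        """Draw a random tiling with exponentially distributed block
        lengths (snapped to integer bp) and i.i.d. states."""
        rng = np.random.default_rng(seed)
        if state_probs is None:
            state_probs = {
                "other_1of3": 0.4,
                "other_2of3": 0.4,
                "LOH_lupina": 0.15,
                "LOH_other": 0.05,
            }
        states = list(state_probs)
        probs = np.array([state_probs[s] for s in states], dtype=float)
        probs = probs / probs.sum()
        blocks: dict[str, list[tuple[int, int, str]]] = {}
        for contig, length in contigs.items():
            cursor = 0
            out = []
            prev_state = None
            while cursor < length:
                size = max(1, int(round(rng.exponential(mean_block_bp))))
                end = min(length, cursor + size)
                state = str(rng.choice(states, p=probs))
                if state == prev_state and len(states) > 1:
                    state = str(rng.choice([s for s in states if s != prev_state]))
                out.append((cursor, end, state))
                prev_state = state
                cursor = end
            blocks[contig] = out
        return cls(contigs=dict(contigs), blocks=blocks, het_density=het_density)

    def state_at(self, contig: str, pos0: np.ndarray) -> np.ndarray:
        """Ancestry state of each 0-based position (vectorised)."""
        blocks = sorted(self.blocks[contig], key=lambda b: b[0])
        starts = np.array([b[0] for b in blocks])
        states = np.array([b[2] for b in blocks])
        idx = np.searchsorted(starts, pos0, side="right") - 1
        return states[idx]


def simulate_hybrid_mosaic(
    spec: MosaicSpec,
    coverage: CoverageModel = CoverageModel(),
    error: ErrorModel = ErrorModel(),
    seed: int = 0,
    dosage_regions: Sequence[tuple[str, int, int, float]] = (),
) -> tuple[SiteCountTable, pd.DataFrame]:
    """Simulate read counts of a triploid hybrid mosaic plus its truth.

    Heterozygous sites are placed uniformly along each contig at the
    spec's density; each inherits the true alternative-allele fraction
    of its ancestry block (0, 1/3, 2/3 or 1).  ``dosage_regions`` lists
    ``(contig, start, end, multiplier)`` intervals whose mean depth is
    scaled, emulating copy-number dosage (e.g. a MAT region present on
    two of three chromosome sets).

    Returns the site table and a truth table with columns ``contig``,
    ``pos0``, ``state``, ``true_fraction``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    truths = []
    for contig, length in spec.contigs.items():
        n = rng.poisson(length * spec.het_density)
        n = min(n, length)
        if n == 0:
            continue
        pos0 = np.sort(rng.choice(length, size=n, replace=False))
        state = spec.state_at(contig, pos0)
        true_f = np.array([STATE_FRACTION[s] for s in state])
        scale = np.ones(n)
        for c, s, e, mult in dosage_regions:
            if c == contig:
                scale[(pos0 >= s) & (pos0 < e)] = mult
        depth = coverage.sample(rng, n, mean_scale=scale)
        alt_depth = rng.binomial(depth, error.observed_fraction(true_f))
        ref, alt = _random_ref_alt(rng, n)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos0": pos0,
                    "ref": ref,
                    "alt": alt,
                    "ref_depth": depth - alt_depth,
                    "alt_depth": alt_depth,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {"contig": contig, "pos0": pos0, "state": state, "true_fraction": true_f}
            )
        )
    empty = pd.DataFrame(columns=SITE_COLUMNS)
    table = SiteCountTable(pd.concat(frames, ignore_index=True) if frames else empty)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["contig", "pos0", "state", "true_fraction"])
    )
    return table, truth


# ---------------------------------------------------------------------------
# multi-taxon ancestry panel
# ---------------------------------------------------------------------------


@dataclass
class AncestryPanel:
    """Output bundle of :func:`simulate_ancestry_panel`.

    ``metagenome`` is the triploid hybrid's site table; ``haploids`` maps
    lineage name to a haploid sample's site table over the same sites;
    ``truth`` carries the per-site ancestry state.  The haploid panel is
    simulated on the species topology ``(((lupina, rugosa), donor),
    outgroup)`` so that the hybrid's "other" subgenome — copied from the
    donor — should resolve as the donor's sister in window genealogies.
    """

    metagenome: SiteCountTable
    haploids: dict[str, SiteCountTable]
    truth: pd.DataFrame
    donor: str
    outgroup: str


def simulate_ancestry_panel(
    spec: MosaicSpec,
    coverage: CoverageModel = CoverageModel(),
    error: ErrorModel = ErrorModel(),
    seed: int = 0,
    donor: str = "vulpina",
    sibling: str = "rugosa",
    outgroup: str = "columbiana",
    divergence: float = 0.12,
    other_private: float = 0.005,
) -> AncestryPanel:
    """Simulate a hybrid metagenome together with a haploid lineage panel.

    Binary alleles evolve on the species tree ``(((lupina, sibling),
    donor), outgroup)`` with per-branch substitution probabilities scaled
    by ``divergence``.  Inside "other" ancestry blocks the hybrid's
    non-reference subgenome carries the donor's allele (plus private
    mutations at rate ``other_private``); inside LOH_lupina blocks it is
    the reference allele.  Only sites where the "other" subgenome differs
    from the reference become variants of the metagenome — the same
    conditioning the real SNP set has.
    """
    rng = np.random.default_rng(seed)
    frames_meta, truths = [], []
    hap_frames: dict[str, list[pd.DataFrame]] = {donor: [], sibling: [], outgroup: []}
    d = divergence
    for contig, length in spec.contigs.items():
        n_cand = rng.poisson(length * spec.het_density * 3)  # pre-conditioning pool
        n_cand = min(n_cand, length)
        pos0 = np.sort(rng.choice(length, size=n_cand, replace=False))
        state = spec.state_at(contig, pos0)
        flip = lambda parent, p: parent ^ (rng.random(n_cand) < p)
        root = np.zeros(n_cand, dtype=bool)
        node_lrd = flip(root, d * 0.6)  # ancestor of (lupina, sibling, donor)
        node_ls = flip(node_lrd, d * 0.8)  # ancestor of (lupina, sibling)
        lup = flip(node_ls, d * 0.7)
        sib = flip(node_ls, d * 0.9)
        don = flip(node_lrd, d)
        out = flip(root, d * 2.5)
        other = flip(don, other_private)
        other = np.where(state == "LOH_lupina", lup, other)
        # condition on the metagenome actually segregating at the site
        keep = other != lup
        if not keep.any():
            continue
        pos0, state = pos0[keep], state[keep]
        alleles = {
            donor: don[keep],
            sibling: sib[keep],
            outgroup: out[keep],
        }
        lup_k, other_k = lup[keep], other[keep]
        n = keep.sum()
        true_f = np.array([STATE_FRACTION[s] for s in state])
        ref, alt = _random_ref_alt(rng, n)
        depth = coverage.sample(rng, n)
        alt_depth = rng.binomial(depth, error.observed_fraction(true_f))
        frames_meta.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos0": pos0,
                    "ref": ref,
                    "alt": alt,
                    "ref_depth": depth - alt_depth,
                    "alt_depth": alt_depth,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {"contig": contig, "pos0": pos0, "state": state, "true_fraction": true_f}
            )
        )
        for name, allele in alleles.items():
            # haploid: homozygous for its own allele, error reads only
            is_alt = allele != lup_k
            h_depth = coverage.sample(rng, n)
            p_obs = error.observed_fraction(is_alt.astype(float))
            h_alt = rng.binomial(h_depth, p_obs)
            hap_frames[name].append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos0": pos0,
                        "ref": ref,
                        "alt": alt,
                        "ref_depth": h_depth - h_alt,
                        "alt_depth": h_alt,
                    }
                )
            )
    empty = pd.DataFrame(columns=SITE_COLUMNS)
    meta = SiteCountTable(
        pd.concat(frames_meta, ignore_index=True) if frames_meta else empty
    )
    haploids = {
        name: SiteCountTable(pd.concat(fr, ignore_index=True) if fr else empty.copy())
        for name, fr in hap_frames.items()
    }
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["contig", "pos0", "state", "true_fraction"])
    )
    return AncestryPanel(
        metagenome=meta, haploids=haploids, truth=truth, donor=donor, outgroup=outgroup
    )


# ---------------------------------------------------------------------------
# idiomorph pairs and mating samples
# ---------------------------------------------------------------------------


def simulate_idiomorph_pair(
    flank_len: int = 1000,
    flank_identity: float = 0.985,
    core_len: int = 3800,
    core_identity: float = 0.48,
    indel_len: int = 129,
    seed: int = 0,
) -> tuple[str, str]:
    """Simulate an aligned MAT idiomorph pair.

    Layout (alignment coordinates): a 5' flank of ``flank_len`` columns
    at ``flank_identity``, a divergent core of ``core_len`` columns at
    ``core_identity``, an indel of ``indel_len`` columns present in the
    second (MAT1-2-like) sequence only — gap characters in the first —
    and a 3' flank.  Returns ``(mat11_like, mat12_like)`` gapped strings
    of equal aligned length.  The idiomorphic region of the first
    sequence therefore runs from column ``flank_len`` to the 3' end of
    the indel at ``flank_len + core_len + indel_len``.
    """
    for name, v in (("flank_len", flank_len), ("core_len", core_len)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if indel_len < 0:
        raise ValueError("indel_len must be non-negative")
    for name, v in (("flank_identity", flank_identity), ("core_identity", core_identity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if core_identity > flank_identity:
        raise ValueError("core_identity must not exceed flank_identity")
    rng = np.random.default_rng(seed)

    def segment(n: int, identity: float) -> tuple[np.ndarray, np.ndarray]:
        a = _BASES[rng.integers(0, 4, size=n)]
        b = a.copy()
        mism = rng.random(n) >= identity
        shift = rng.integers(1, 4, size=n)
        idx_b = (np.searchsorted(_BASES, b) + shift) % 4
        b[mism] = _BASES[idx_b[mism]]
        return a, b

    a5, b5 = segment(flank_len, flank_identity)
    ac, bc = segment(core_len, core_identity)
    b_indel = _BASES[rng.integers(0, 4, size=indel_len)]
    a_indel = np.full(indel_len, "-")
    a3, b3 = segment(flank_len, flank_identity)
    seq_a = "".join(np.concatenate([a5, ac, a_indel, a3]))
    seq_b = "".join(np.concatenate([b5, bc, b_indel, b3]))
    return seq_a, seq_b


def simulate_mating_sample(
    n: int,
    p_mat11: float,
    seed: int = 0,
    region: str = "sim",
    species: str = "sim",
) -> MatingTypeCounts:
    """Binomial draw of MAT1-1 thalli among ``n``; the rest are MAT1-2."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= p_mat11 <= 1:
        raise ValueError("p_mat11 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n, p_mat11))
    return MatingTypeCounts(region=region, species=species, n_mat11=k, n_mat12=n - k)
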