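"""Forward simulator of recombination-driven genome-size change.

The model: the local recombination rate c(p) is a property of chromosomal
*location* — minimal at the centromere and rising steeply toward each
telomere. Deletions (mostly homology-free "illegitimate" events, plus a
minority of unequal intrastrand recombination events between the two
terminal repeats of intact LTR retrotransposons) occur with intensity
proportional to c(p), while new TE insertions accumulate preferentially
where recombination is low, with intensity proportional to 1 - c(p)/max c.
Sequence loss in high-recombination regions therefore outpaces gain in
low-recombination regions. A rearrangement (inversion, relocation) that
moves repeat-rich pericentromeric material into a distal, high-recombination
environment exposes it to rapid removal and shrinks the rearranged region.

Chromosomes are ordered, gap-free tilings of gene / TE / spacer features.
Every feature carries provenance back to the ancestral sequence it derives
from, which lets the synthetic-data layer emit exact whole-genome alignment
blocks without running an aligner, and lets truth replay reproduce a final
genome from the ancestor plus the event log.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import BoundsError, ConfigError, DataError, ProtectedBreakpointError

TE_CLASSES = ("DNA", "LTR", "LINE", "SINE", "low_complexity", "simple_repeat", "other")

#: src ids at or above this value denote sequence inserted after the split
#: (unique per lineage); below it, ancestral sequence shared by both lineages.
INSERT_SRC_BASE = 10_000_000

#: TE fragments shorter than this lose their annotation (the sequence stays,
#: re-tiled as spacer): repeat annotation does not recover arbitrarily small
#: element relics, and keeping them as "TEs" would let fragmentation inflate
#: element counts in heavily deleted regions.
MIN_ANNOTATED_TE_FRAGMENT = 200


def _sigmoid(x: float) -> float:
    if x >= 0:
        z = math.exp(-x)
        return 1.0 / (1.0 + z)
    z = math.exp(x)
    return z / (1.0 + z)


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinationMap:
    """Location-dependent relative recombination rate c(p).

    A symmetric logistic ramp runs from the centromere out to each telomere:
    within an arm, with d the fractional distance from the centromere,

        c = c_min + (c_max - c_min) * (s(d) - s(0)) / (s(1) - s(0)),
        s(d) = logistic((d - ramp_midpoint) / ramp_width).

    This stays near c_min across the pericentromere and rises rapidly in the
    distal portion of the arm, matching Marey-map profiles in which genetic
    distance is flat proximally and climbs steeply near the telomeres.
    c is non-increasing from each telomere toward the centromere and minimal
    at the centromere. ``total_map_length_cM`` fixes the genetic length used
    when converting the profile into cumulative centimorgans.
    """

    chromosome_length: int
    centromere_position: int
    ramp_midpoint: float = 0.68
    ramp_width: float = 0.07
    c_min: float = 0.01
    c_max: float = 1.0
    total_map_length_cM: float = 120.0

    def __post_init__(self) -> None:
        if not (0 <= self.centromere_position <= self.chromosome_length):
            raise ConfigError("centromere_position outside chromosome")
        if self.c_min < 0 or self.c_max < self.c_min:
            raise ConfigError("require 0 <= c_min <= c_max")
        if self.ramp_width <= 0:
            raise ConfigError("ramp_width must be positive")

    # -- scalar fast path (hot loop in the simulator) -----------------------

    def _norm_consts(self) -> tuple[float, float]:
        lo = _sigmoid(-self.ramp_midpoint / self.ramp_width)
        hi = _sigmoid((1.0 - self.ramp_midpoint) / self.ramp_width)
        return lo, hi

    def rate_from_d(self, d: float) -> float:
        """c as a function of the fractional distance d from the centromere."""
        lo, hi = self._norm_consts()
        s = (_sigmoid((d - self.ramp_midpoint) / self.ramp_width) - lo) / (hi - lo)
        return self.c_min + (self.c_max - self.c_min) * s

    def rate_scalar(self, position: float) -> float:
        L = self.chromosome_length
        cen = self.centromere_position
        arm = cen if position < cen else L - cen
        d = 1.0 if arm <= 0 else abs(position - cen) / arm
        return self.rate_from_d(d)

    def rate_at(self, positions):
        """Vectorised c(p); raises :class:`BoundsError` outside [0, L)."""
        p = np.asarray(positions, dtype=float)
        if np.any(p < 0) or np.any(p >= self.chromosome_length):
            raise BoundsError(
                f"position outside [0, {self.chromosome_length}) for this map"
            )
        cen = float(self.centromere_position)
        L = float(self.chromosome_length)
        left = max(cen, 1.0)
        right = max(L - cen, 1.0)
        arm = np.where(p < cen, left, right)
        d = np.abs(p - cen) / arm
        lo, hi = self._norm_consts()
        with np.errstate(over="ignore"):
            s = (1.0 / (1.0 + np.exp(-(d - self.ramp_midpoint) / self.ramp_width)) - lo) / (
                hi - lo
            )
        c = self.c_min + (self.c_max - self.c_min) * s
        if np.isscalar(positions) or np.ndim(positions) == 0:
            return float(c)
        return c

    def genetic_position(self, positions, n_grid: int = 4096):
        """Cumulative genetic distance (cM) at physical positions.

        The integral of c is computed by trapezoid quadrature on a dense grid
        and rescaled so the chromosome spans ``total_map_length_cM``.
        """
        from scipy.integrate import cumulative_trapezoid

        grid = np.linspace(0.0, self.chromosome_length - 1, n_grid)
        c = self.rate_at(grid)
        cum = np.concatenate([[0.0], cumulative_trapezoid(c, grid)])
        total = cum[-1]
        if total <= 0:
            cum = grid.astype(float)
            total = cum[-1]
        cm = cum / total * self.total_map_length_cM
        out = np.interp(np.asarray(positions, dtype=float), grid, cm)
        if np.isscalar(positions) or np.ndim(positions) == 0:
            return float(out)
        return out


def recombination_rate_at(recomb_map: RecombinationMap, position: float) -> float:
    """Relative recombination rate c at ``position`` (bounds-checked)."""
    if not (0 <= position < recomb_map.chromosome_length):
        raise BoundsError(
            f"position {position} outside [0, {recomb_map.chromosome_length})"
        )
    return recomb_map.rate_scalar(position)


# ---------------------------------------------------------------------------
# Features and chromosome state
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """One tile of a chromosome: a gene, a TE copy, or intergenic spacer.

    ``ltr_termini`` holds (5' length, 3' length) for intact LTR
    retrotransposons, oriented with the element's strand; ``is_solo_ltr``
    marks a lone terminal repeat left behind by unequal intrastrand
    recombination. ``src`` is provenance: (ancestral copy id, lo, hi) —
    the half-open slice of that ancestral copy this feature still carries;
    ``flipped`` records whether the slice runs reverse-complemented relative
    to the ancestor.
    """

    kind: str  # "gene" | "te" | "spacer"
    start: int
    end: int
    strand: str = "+"
    family_id: Optional[str] = None
    te_class: Optional[str] = None
    ltr_termini: Optional[tuple[int, int]] = None
    is_solo_ltr: bool = False
    src: Optional[tuple[int, int, int]] = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(f"feature with start {self.start} >= end {self.end}")
        if self.ltr_termini is not None:
            if self.te_class != "LTR":
                raise DataError("ltr_termini requires te_class='LTR'")
            if self.is_solo_ltr:
                raise DataError("a solo LTR cannot carry a termini pair")
            t5, t3 = self.ltr_termini
            if t5 + t3 > self.length:
                raise DataError("LTR termini do not fit inside the element")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_intact_ltr(self) -> bool:
        return self.ltr_termini is not None

    def terminus_intervals(self) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
        """Absolute (5'LTR, 3'LTR) intervals, honouring the element strand."""
        if self.ltr_termini is None:
            return None
        t5, t3 = self.ltr_termini
        if self.strand == "+":
            return ((self.start, self.start + t5), (self.end - t3, self.end))
        return ((self.end - t5, self.end), (self.start, self.start + t3))

    def anc_interval(self, a: int, b: int) -> Optional[tuple[int, int, int]]:
        """Ancestral source slice for the current sub-interval [a, b)."""
        if self.src is None:
            return None
        sid, lo, hi = self.src
        offs, offe = a - self.start, b - self.start
        if self.flipped:
            return (sid, hi - offe, hi - offs)
        return (sid, lo + offs, lo + offe)

    def copy(self) -> "Feature":
        return replace(self)


@dataclass
class EventRecord:
    """One logged mutational or structural event on a chromosome.

    ``span`` is in the coordinates that were current when the event was
    applied; replaying the log in order therefore reproduces the final
    chromosome from the ancestor. ``detail`` carries mechanism evidence:
    the retained solo-LTR interval for unequal intrastrand deletions, the
    removed ancestral-source slices for deletions, and the full feature
    specification for insertions.
    """

    generation: int
    kind: str
    span: tuple[int, int]
    length_change: int
    detail: dict = field(default_factory=dict)


@dataclass
class ChromosomeState:
    """Ordered, gap-free feature tiling of one simulated chromosome."""

    name: str
    features: list[Feature]
    length: int
    recomb: RecombinationMap
    generation: int = 0
    log: list[EventRecord] = field(default_factory=list)
    next_src_id: int = INSERT_SRC_BASE
    centromere: int = -1

    def __post_init__(self) -> None:
        if self.centromere < 0:
            self.centromere = self.recomb.centromere_position

    def validate(self) -> None:
        pos = 0
        for f in self.features:
            if f.start != pos:
                raise DataError(f"{self.name}: tiling gap/overlap at {pos}")
            pos = f.end
        if pos != self.length:
            raise DataError(f"{self.name}: features tile {pos} != length {self.length}")

    def rate_at(self, position: float) -> float:
        """c at a position of the *current* chromosome.

        The centromere is a physical locus: structural events shift it only
        when they add or remove sequence on its left, so the recombination
        landscape of an arm responds to that arm's own length changes and
        not to the other arm's.
        """
        if self.length <= 0:
            return self.recomb.c_min
        cen = min(max(self.centromere, 0), self.length)
        arm = cen if position < cen else self.length - cen
        d = 1.0 if arm <= 0 else abs(position - cen) / arm
        return self.recomb.rate_from_d(min(d, 1.0))

    def gene_bp(self) -> int:
        return sum(f.length for f in self.features if f.kind == "gene")

    def intact_ltr_features(self) -> list[Feature]:
        return [f for f in self.features if f.is_intact_ltr]

    def feature_index_at(self, position: int) -> int:
        if not (0 <= position < self.length):
            raise BoundsError(f"{self.name}: position {position} out of range")
        lo, hi = 0, len(self.features) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if self.features[mid].end <= position:
                lo = mid + 1
            else:
                hi = mid
        return lo


def _retile(chrom: ChromosomeState) -> None:
    pos = 0
    for f in chrom.features:
        ln = f.end - f.start
        f.start = pos
        f.end = pos + ln
        pos += ln
    chrom.length = pos


def clone_chromosome(
    chrom: ChromosomeState, name: Optional[str] = None, src_base: Optional[int] = None
) -> ChromosomeState:
    return ChromosomeState(
        name=name or chrom.name,
        features=[f.copy() for f in chrom.features],
        length=chrom.length,
        recomb=chrom.recomb,
        generation=chrom.generation,
        log=[],
        next_src_id=src_base if src_base is not None else chrom.next_src_id,
        centromere=chrom.centromere,
    )


def features_equal(a: Sequence[Feature], b: Sequence[Feature]) -> bool:
    return list(a) == list(b)


# ---------------------------------------------------------------------------
# Family registry and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """Template metadata for a gene family or TE family."""

    family_id: str
    kind: str  # "gene" | "te"
    te_class: Optional[str]
    length: int
    term_len: int = 0  # LTR terminal-repeat length (LTR families only)
    index: int = 0  # stable key for template-sequence streams


class FamilyRegistry:
    """Deterministic registry of the family templates in play."""

    def __init__(self) -> None:
        self.families: dict[str, FamilySpec] = {}
        self.by_class: dict[str, list[str]] = defaultdict(list)
        self._n = 0

    def add(
        self,
        family_id: str,
        kind: str,
        length: int,
        te_class: Optional[str] = None,
        term_len: int = 0,
    ) -> FamilySpec:
        if family_id in self.families:
            return self.families[family_id]
        spec = FamilySpec(family_id, kind, te_class, int(length), int(term_len), self._n)
        self.families[family_id] = spec
        if te_class is not None:
            self.by_class[te_class].append(family_id)
        self._n += 1
        return spec

    def __getitem__(self, family_id: str) -> FamilySpec:
        return self.families[family_id]

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.families

    def sample_te(self, rng: np.random.Generator, class_weights: dict[str, float]) -> FamilySpec:
        classes = [c for c in class_weights if class_weights[c] > 0 and self.by_class[c]]
        if not classes:
            raise ConfigError("no TE families available to sample from")
        w = np.array([class_weights[c] for c in classes], dtype=float)
        w /= w.sum()
        cls = classes[int(rng.choice(len(classes), p=w))]
        fams = self.by_class[cls]
        return self.families[fams[int(rng.integers(0, len(fams)))]]


DEFAULT_TE_CLASS_WEIGHTS: dict[str, float] = {
    "LTR": 0.45,
    "DNA": 0.20,
    "LINE": 0.12,
    "SINE": 0.05,
    "simple_repeat": 0.10,
    "low_complexity": 0.08,
}

DEFAULT_TE_FAMILY_COUNTS: dict[str, int] = {
    "LTR": 14,
    "DNA": 10,
    "LINE": 6,
    "SINE": 3,
    "simple_repeat": 3,
    "low_complexity": 3,
}


@dataclass
class SimConfig:
    """Study conditions for a simulated genome pair.

    Lengths are desk-scale (hundreds of kb per chromosome) rather than the
    >100 Mbp of real legume chromosomes; the event rates are calibrated so
    that, over ``n_generations``, a terminal inversion reproduces the
    qualitative and headline quantitative outcome of the model — an
    inverted-region size ratio well above 1 alongside near-unity
    non-inverted ratios — while remaining fast enough for replicate runs.

    Rates (all per generation):
      * ``lambda_illegit`` — illegitimate deletions per bp per unit c(p).
      * ``lambda_unequal`` — unequal intrastrand events per intact LTR
        element per unit c at the element midpoint; each converts the
        element into a solo LTR.
      * ``lambda_insert`` — TE insertions per bp, thinned by 1 - c/c_max.

    Deletion lengths follow a truncated discrete power law so that short
    deletions dominate event counts while long (>=1 kb) ones dominate the
    total bp removed.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 1_200_000
    centromere_fraction: float = 0.5
    ramp_midpoint: float = 0.72
    ramp_width: float = 0.05
    c_min: float = 0.01
    c_max: float = 1.0
    total_map_length_cM: float = 120.0
    # U-shaped gene gradient / anti-correlated TE gradient
    gene_weight_min: float = 0.06
    gene_weight_max: float = 0.80
    te_weight_min: float = 0.05
    te_weight_max: float = 0.82
    density_exponent: float = 1.5
    tandem_dup_prob: float = 0.06
    te_class_weights: dict = field(default_factory=lambda: dict(DEFAULT_TE_CLASS_WEIGHTS))
    te_family_counts: dict = field(default_factory=lambda: dict(DEFAULT_TE_FAMILY_COUNTS))
    gene_length_range: tuple[int, int] = (1500, 4000)
    spacer_length_range: tuple[int, int] = (300, 1800)
    # event rates
    lambda_illegit: float = 1.8e-6
    lambda_unequal: float = 2.0e-3
    lambda_insert: float = 4.0e-9
    deletion_alpha: float = 1.6
    deletion_min_len: int = 30
    deletion_max_len: int = 20_000
    gene_protection: bool = True
    rng_seed: int = 0
    n_generations: int = 2500

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if min(self.lambda_illegit, self.lambda_unequal, self.lambda_insert) < 0:
            raise ConfigError("event rates must be non-negative")
        if self.deletion_min_len < 1 or self.deletion_max_len < self.deletion_min_len:
            raise ConfigError("deletion length support must be >= 1 bp")
        if not 0 < self.centromere_fraction < 1:
            raise ConfigError("centromere_fraction must lie in (0, 1)")

    def recomb_map(self) -> RecombinationMap:
        return RecombinationMap(
            chromosome_length=self.chromosome_length,
            centromere_position=int(self.chromosome_length * self.centromere_fraction),
            ramp_midpoint=self.ramp_midpoint,
            ramp_width=self.ramp_width,
            c_min=self.c_min,
            c_max=self.c_max,
            total_map_length_cM=self.total_map_length_cM,
        )

    def get_registry(self) -> FamilyRegistry:
        """TE family registry, deterministic in ``rng_seed``; cached."""
        reg = getattr(self, "_registry", None)
        if reg is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.rng_seed, 101]))
            reg = build_family_registry(rng, self)
            object.__setattr__(self, "_registry", reg)
        return reg


def build_family_registry(rng: np.random.Generator, config: SimConfig) -> FamilyRegistry:
    reg = FamilyRegistry()
    ranges = {
        "DNA": (500, 3000),
        "LINE": (800, 3000),
        "SINE": (150, 400),
        "simple_repeat": (100, 600),
        "low_complexity": (100, 600),
        "other": (200, 1500),
    }
    for cls, n_fam in config.te_family_counts.items():
        for i in range(n_fam):
            fam = f"{cls}_fam{i:02d}"
            if cls == "LTR":
                term = int(rng.integers(200, 351))
                internal = int(rng.integers(1500, 3501))
                reg.add(fam, "te", 2 * term + internal, te_class=cls, term_len=term)
            else:
                lo, hi = ranges.get(cls, (200, 1500))
                reg.add(fam, "te", int(rng.integers(lo, hi + 1)), te_class=cls)
    return reg


# ---------------------------------------------------------------------------
# Deletion-length distribution
# ---------------------------------------------------------------------------


class _DeletionSampler:
    """Truncated discrete power law over [min_len, max_len]."""

    def __init__(self, alpha: float, lmin: int, lmax: int) -> None:
        lengths = np.arange(lmin, lmax + 1, dtype=float)
        w = lengths**-alpha
        self.lengths = lengths.astype(int)
        p = w / w.sum()
        self.cdf = np.cumsum(p)
        self.mean = float((lengths * p).sum())

    def draw(self, rng: np.random.Generator) -> int:
        return int(self.lengths[int(np.searchsorted(self.cdf, rng.random()))])


def deletion_sampler(config: SimConfig) -> _DeletionSampler:
    key = (config.deletion_alpha, config.deletion_min_len, config.deletion_max_len)
    cached = getattr(config, "_del_sampler", None)
    if cached is None or cached[0] != key:
        sampler = _DeletionSampler(*key)
        object.__setattr__(config, "_del_sampler", (key, sampler))
        return sampler
    return cached[1]


def expected_deletion_length(config: SimConfig) -> float:
    return deletion_sampler(config).mean


# ---------------------------------------------------------------------------
# Ancestral chromosome construction
# ---------------------------------------------------------------------------


def build_ancestral_chromosome(
    config: SimConfig,
    chrom_index: int,
    rng: np.random.Generator,
    registry: Optional[FamilyRegistry] = None,
    name: Optional[str] = None,
) -> ChromosomeState:
    """Assemble an ancestral chromosome with the canonical density gradients.

    Walking left to right, each tile is a gene, TE copy, or spacer with
    position-dependent odds: the gene weight rises with fractional distance
    d from the centromere as ``g_min + (g_max - g_min) d^k`` while the TE
    weight falls symmetrically, producing the U-shaped gene-density track
    (high at both telomeres, low pericentromerically) and the anti-correlated
    TE track expected of an unrearranged chromosome. A small tandem
    duplication probability re-uses the previous gene family so that local
    gene duplications exist.
    """
    config.validate()
    L = config.chromosome_length
    if chrom_index >= config.n_chromosomes:
        raise ConfigError("chrom_index out of range")
    min_needed = config.gene_length_range[0] + 500
    if L < max(4000, min_needed):
        raise ConfigError(
            f"chromosome of {L} bp too short to place at least one gene and one TE"
        )
    registry = registry if registry is not None else config.get_registry()
    recomb = config.recomb_map()
    cen = recomb.centromere_position

    features: list[Feature] = []
    pos = 0
    src_id = chrom_index * 1_000_000
    gene_counter = 0
    prev_gene_family: Optional[str] = None
    te_total_weight = sum(config.te_class_weights.values())

    while pos < L:
        arm = cen if pos < cen else L - cen
        d = 1.0 if arm <= 0 else abs(pos - cen) / arm
        dk = d**config.density_exponent
        wg = config.gene_weight_min + (config.gene_weight_max - config.gene_weight_min) * dk
        wt = config.te_weight_max - (config.te_weight_max - config.te_weight_min) * dk
        if te_total_weight <= 0:
            wt = 0.0
        roll = rng.random()
        strand = "+" if rng.random() < 0.5 else "-"
        if roll < wg:
            if prev_gene_family is not None and rng.random() < config.tandem_dup_prob:
                fam = prev_gene_family
                flen = registry[fam].length
            else:
                fam = f"g{chrom_index:02d}_{gene_counter:05d}"
                gene_counter += 1
                flen = int(rng.integers(*config.gene_length_range))
                registry.add(fam, "gene", flen)
            prev_gene_family = fam
            feat = Feature("gene", pos, pos + flen, strand, family_id=fam)
        elif roll < wg + wt:
            spec = registry.sample_te(rng, config.te_class_weights)
            flen = spec.length
            termini = (spec.term_len, spec.term_len) if spec.te_class == "LTR" else None
            feat = Feature(
                "te",
                pos,
                pos + flen,
                strand,
                family_id=spec.family_id,
                te_class=spec.te_class,
                ltr_termini=termini,
            )
        else:
            flen = int(rng.integers(*config.spacer_length_range))
            feat = Feature("spacer", pos, pos + flen, "+")
        if feat.end > L:  # truncate the final tile at the chromosome end
            feat.end = L
            if feat.is_intact_ltr:
                feat.ltr_termini = None
            if feat.length <= 0:
                break
        feat.src = (src_id, 0, feat.length)
        src_id += 1
        features.append(feat)
        pos = feat.end

    chrom = ChromosomeState(
        name=name or f"chr{chrom_index + 1:02d}",
        features=features,
        length=L,
        recomb=recomb,
        next_src_id=INSERT_SRC_BASE,
    )
    chrom.validate()
    return chrom


# ---------------------------------------------------------------------------
# Structural editing primitives
# ---------------------------------------------------------------------------


def _degrade_small_fragment(frag: Feature) -> Feature:
    if frag.kind == "te" and frag.length < MIN_ANNOTATED_TE_FRAGMENT:
        frag.kind = "spacer"
        frag.family_id = None
        frag.te_class = None
        frag.is_solo_ltr = False
    return frag


def _cut_feature(feat: Feature, position: int) -> tuple[Feature, Feature]:
    """Split ``feat`` at an internal absolute position; termini metadata of
    intact LTR elements does not survive fragmentation, and fragments below
    the annotation threshold degrade to plain sequence."""
    assert feat.start < position < feat.end
    left = feat.copy()
    right = feat.copy()
    left.end = position
    right.start = position
    left.src = feat.anc_interval(feat.start, position)
    right.src = feat.anc_interval(position, feat.end)
    if feat.is_intact_ltr:
        left.ltr_termini = None
        right.ltr_termini = None
    return _degrade_small_fragment(left), _degrade_small_fragment(right)


def _split_at(chrom: ChromosomeState, position: int, gene_protection: bool) -> None:
    """Ensure ``position`` is a feature boundary, splitting a TE/spacer if
    needed. Splitting a gene is refused under gene protection."""
    if position in (0, chrom.length):
        return
    idx = chrom.feature_index_at(position)
    feat = chrom.features[idx]
    if feat.start == position:
        return
    if feat.kind == "gene" and gene_protection:
        raise ProtectedBreakpointError(
            f"{chrom.name}: breakpoint {position} falls inside gene {feat.family_id}"
        )
    left, right = _cut_feature(feat, position)
    chrom.features[idx : idx + 1] = [left, right]


def _overlaps_gene(chrom: ChromosomeState, s: int, e: int) -> bool:
    return any(f.kind == "gene" and f.start < e and f.end > s for f in chrom.features)


def delete_span(
    chrom: ChromosomeState,
    start: int,
    end: int,
    kind: str = "illegitimate_deletion",
    record: bool = True,
    detail: Optional[dict] = None,
) -> EventRecord:
    """Remove [start, end) from the chromosome, fragmenting edge features.

    The removed ancestral-source slices are collected into the event record
    so that deletion truth is recoverable in ancestral coordinates.
    """
    if not (0 <= start < end <= chrom.length):
        raise BoundsError(f"{chrom.name}: bad deletion span [{start}, {end})")
    removed_src: list[tuple[int, int, int]] = []
    new_features: list[Feature] = []
    for f in chrom.features:
        if f.end <= start or f.start >= end:
            new_features.append(f)
            continue
        cut_lo, cut_hi = max(f.start, start), min(f.end, end)
        anc = f.anc_interval(cut_lo, cut_hi)
        if anc is not None:
            removed_src.append(anc)
        if f.start < cut_lo:
            left = f.copy()
            left.end = cut_lo
            left.src = f.anc_interval(f.start, cut_lo)
            if f.is_intact_ltr:
                left.ltr_termini = None
            new_features.append(_degrade_small_fragment(left))
        if f.end > cut_hi:
            right = f.copy()
            right.start = cut_hi
            right.src = f.anc_interval(cut_hi, f.end)
            if f.is_intact_ltr:
                right.ltr_termini = None
            new_features.append(_degrade_small_fragment(right))
    chrom.features = new_features
    if end <= chrom.centromere:
        chrom.centromere -= end - start
    elif start < chrom.centromere:
        chrom.centromere = start
    _retile(chrom)
    ev = EventRecord(
        generation=chrom.generation,
        kind=kind,
        span=(start, end),
        length_change=-(end - start),
        detail={**(detail or {}), "removed_src": removed_src},
    )
    if record:
        chrom.log.append(ev)
    return ev


def convert_to_solo(chrom: ChromosomeState, feature: Feature, record: bool = True) -> EventRecord:
    """Unequal intrastrand recombination between an element's two LTRs.

    The 5' terminal repeat (in the element's own orientation) is retained as
    a solo LTR; the internal region and the other terminus are removed.
    """
    if not feature.is_intact_ltr:
        raise DataError("convert_to_solo requires an intact LTR element")
    t5, _t3 = feature.ltr_termini
    fs, fe = feature.start, feature.end
    if feature.strand == "+":
        keep = (fs, fs + t5)
        cut = (fs + t5, fe)
    else:
        keep = (fe - t5, fe)
        cut = (fs, fe - t5)
    solo = Feature(
        "te",
        keep[0],
        keep[1],
        feature.strand,
        family_id=feature.family_id,
        te_class="LTR",
        is_solo_ltr=True,
        src=feature.anc_interval(*keep),
        flipped=feature.flipped,
    )
    removed_src = [feature.anc_interval(*cut)] if feature.src else []
    idx = chrom.features.index(feature)
    chrom.features[idx] = solo
    if cut[1] <= chrom.centromere:
        chrom.centromere -= cut[1] - cut[0]
    elif cut[0] < chrom.centromere:
        chrom.centromere = cut[0]
    _retile(chrom)
    ev = EventRecord(
        generation=chrom.generation,
        kind="unequal_intrastrand_deletion",
        span=(fs, fe),
        length_change=-(cut[1] - cut[0]),
        detail={
            "solo_interval": keep,
            "solo_src": solo.src,
            "removed_src": [s for s in removed_src if s is not None],
            "family_id": feature.family_id,
        },
    )
    if record:
        chrom.log.append(ev)
    return ev


def insert_feature(
    chrom: ChromosomeState,
    position: int,
    feat: Feature,
    gene_protection: bool = True,
    record: bool = True,
) -> EventRecord:
    """Insert a new feature at ``position``, splitting the host tile."""
    if not (0 <= position <= chrom.length):
        raise BoundsError(f"{chrom.name}: insertion point {position} out of range")
    _split_at(chrom, position, gene_protection)
    idx = (
        len(chrom.features)
        if position == chrom.length
        else chrom.feature_index_at(position)
    )
    new = feat.copy()
    new.start, new.end = position, position + feat.length
    chrom.features.insert(idx, new)
    if position <= chrom.centromere:
        chrom.centromere += feat.length
    _retile(chrom)
    ev = EventRecord(
        generation=chrom.generation,
        kind="insertion",
        span=(position, position + feat.length),
        length_change=feat.length,
        detail={"feature": new.copy()},
    )
    if record:
        chrom.log.append(ev)
    return ev


def apply_inversion(
    chrom: ChromosomeState,
    start: int,
    end: int,
    gene_protection: bool = True,
    record: bool = True,
) -> ChromosomeState:
    """Invert [start, end): features reversed in order, strands flipped.

    Breakpoints strictly inside a TE/spacer split it (fragments keep their
    family identity); a breakpoint inside a gene raises
    :class:`ProtectedBreakpointError` under gene protection.
    """
    if not (0 <= start < end <= chrom.length):
        raise BoundsError(f"{chrom.name}: bad inversion span [{start}, {end})")
    _split_at(chrom, start, gene_protection)
    _split_at(chrom, end, gene_protection)
    i = chrom.feature_index_at(start) if start < chrom.length else len(chrom.features)
    j = chrom.feature_index_at(end) if end < chrom.length else len(chrom.features)
    seg = chrom.features[i:j][::-1]
    for f in seg:
        f.strand = "-" if f.strand == "+" else "+"
        f.flipped = not f.flipped
    chrom.features[i:j] = seg
    if start < chrom.centromere < end:
        chrom.centromere = start + end - chrom.centromere
    _retile(chrom)
    if record:
        chrom.log.append(
            EventRecord(chrom.generation, "inversion", (start, end), 0, {})
        )
    return chrom


def snap_to_boundary(chrom: ChromosomeState, position: int) -> int:
    """Nearest feature boundary to ``position``."""
    position = min(max(position, 0), chrom.length)
    if position in (0, chrom.length):
        return position
    f = chrom.features[chrom.feature_index_at(position)]
    return f.start if position - f.start <= f.end - position else f.end


def apply_relocation(
    chrom_a: ChromosomeState,
    span: tuple[int, int],
    chrom_b: ChromosomeState,
    insert_at: int,
    gene_protection: bool = True,
    record: bool = True,
) -> tuple[ChromosomeState, ChromosomeState]:
    """Move the features of ``span`` on A to ``insert_at`` on B.

    Total bp across the two chromosomes is conserved; moved features keep
    kind/family/strand. Works for A is B (intra-chromosomal relocation);
    relocating a span onto its own start position is the identity.
    """
    s, e = span
    if not (0 <= s < e <= chrom_a.length):
        raise BoundsError(f"{chrom_a.name}: bad relocation span [{s}, {e})")
    same = chrom_a is chrom_b
    if same and s <= insert_at < e and insert_at != s:
        raise DataError("insertion point lies inside the moved span")
    _split_at(chrom_a, s, gene_protection)
    _split_at(chrom_a, e, gene_protection)
    i = chrom_a.feature_index_at(s)
    j = chrom_a.feature_index_at(e) if e < chrom_a.length else len(chrom_a.features)
    moved = chrom_a.features[i:j]
    del chrom_a.features[i:j]
    if e <= chrom_a.centromere:
        chrom_a.centromere -= e - s
    elif s < chrom_a.centromere:
        chrom_a.centromere = s
    _retile(chrom_a)
    if same and insert_at >= e:
        insert_at -= e - s
    _split_at(chrom_b, insert_at, gene_protection)
    k = (
        len(chrom_b.features)
        if insert_at == chrom_b.length
        else chrom_b.feature_index_at(insert_at)
    )
    chrom_b.features[k:k] = moved
    moved_len = e - s
    if insert_at <= chrom_b.centromere:
        chrom_b.centromere += moved_len
    _retile(chrom_b)
    if record:
        chrom_a.log.append(
            EventRecord(
                chrom_a.generation,
                "relocation",
                (s, e),
                0,
                {"role": "source", "target": chrom_b.name, "insert_at": insert_at,
                 "moved_bp": moved_len},
            )
        )
        if not same:
            chrom_b.log.append(
                EventRecord(
                    chrom_b.generation,
                    "relocation",
                    (insert_at, insert_at + moved_len),
                    0,
                    {"role": "target", "source": chrom_a.name, "moved_bp": moved_len},
                )
            )
    return chrom_a, chrom_b


# ---------------------------------------------------------------------------
# Per-generation dynamics
# ---------------------------------------------------------------------------


def step_generation(
    chrom: ChromosomeState,
    config: SimConfig,
    rng: np.random.Generator,
    registry: Optional[FamilyRegistry] = None,
) -> ChromosomeState:
    """Advance one generation of thinned-Poisson deletion/insertion dynamics.

    Event counts are drawn Poisson at the chromosome length current at the
    start of the generation; candidate positions are thinned by c(p)/c_max
    (deletions) or 1 - c(p)/c_max (insertions), which is exact in the
    small-rate limit. Under gene protection a deletion overlapping any gene
    bp is re-drawn up to 10 times and then skipped, and insertions land only
    in spacer/TE tiles.
    """
    cmax = chrom.recomb.c_max
    gen = chrom.generation
    L0 = chrom.length

    if config.lambda_illegit > 0 and L0 > 0 and cmax > 0:
        sampler = deletion_sampler(config)
        n_prop = rng.poisson(config.lambda_illegit * cmax * L0)
        for _ in range(n_prop):
            for _attempt in range(10):
                L = chrom.length
                if L <= 1:
                    break
                pos = int(rng.integers(0, L))
                if rng.random() >= chrom.rate_at(pos) / cmax:
                    continue
                dlen = sampler.draw(rng)
                s, e = pos, min(pos + dlen, L)
                if e - s < 1:
                    continue
                if config.gene_protection and _overlaps_gene(chrom, s, e):
                    continue
                delete_span(chrom, s, e, kind="illegitimate_deletion")
                ev = chrom.log[-1]
                ev.generation = gen
                break

    if config.lambda_unequal > 0:
        for f in list(chrom.intact_ltr_features()):
            mid = (f.start + f.end) // 2
            p = config.lambda_unequal * chrom.rate_at(mid)
            if rng.random() < p:
                ev = convert_to_solo(chrom, f)
                ev.generation = gen

    if config.lambda_insert > 0 and cmax > 0:
        reg = registry if registry is not None else config.get_registry()
        n_ins = rng.poisson(config.lambda_insert * chrom.length)
        for _ in range(n_ins):
            for _attempt in range(10):
                pos = int(rng.integers(0, chrom.length + 1))
                probe = min(pos, chrom.length - 1)
                if rng.random() >= 1.0 - chrom.rate_at(probe) / cmax:
                    continue
                if 0 < pos < chrom.length:
                    host = chrom.features[chrom.feature_index_at(pos)]
                    if host.kind == "gene" and host.start < pos:
                        continue
                spec = reg.sample_te(rng, config.te_class_weights)
                termini = (spec.term_len, spec.term_len) if spec.te_class == "LTR" else None
                sid = chrom.next_src_id
                chrom.next_src_id += 1
                feat = Feature(
                    "te",
                    0,
                    spec.length,
                    "+" if rng.random() < 0.5 else "-",
                    family_id=spec.family_id,
                    te_class=spec.te_class,
                    ltr_termini=termini,
                    src=(sid, 0, spec.length),
                )
                ev = insert_feature(chrom, pos, feat, config.gene_protection)
                ev.generation = gen
                break

    chrom.generation = gen + 1
    return chrom


# ---------------------------------------------------------------------------
# Divergent pair simulation and truth replay
# ---------------------------------------------------------------------------


@dataclass
class DivergentPair:
    """Two genomes evolved independently from a common ancestor.

    Lineage D carries the planned rearrangements (applied at generation 0);
    lineage I retains the ancestral architecture. ``ancestors`` is the
    pristine common ancestor, kept for truth replay and for deriving exact
    alignment blocks from feature provenance.
    """

    config: SimConfig
    registry: FamilyRegistry
    ancestors: list[ChromosomeState]
    genome_I: list[ChromosomeState]
    genome_D: list[ChromosomeState]

    def lineage(self, which: str) -> list[ChromosomeState]:
        return self.genome_I if which == "I" else self.genome_D


def terminal_inversion_plan(
    config: SimConfig, chrom_index: int = 0, start_fraction: float = 0.52
) -> list[tuple[int, tuple[int, int]]]:
    """One inversion from ``start_fraction`` of the chromosome to its end —
    the canonical scenario exposing pericentromeric material distally."""
    L = config.chromosome_length
    return [(chrom_index, (int(L * start_fraction), L))]


def simulate_divergent_pair(
    config: SimConfig,
    inversion_plan: Optional[list[tuple[int, tuple[int, int]]]] = None,
) -> DivergentPair:
    """Evolve lineages I and D from a shared ancestor.

    The two lineages (and each chromosome within a lineage) consume
    independent child streams of the seed, so lineage I's trajectory is
    unaffected by how many draws lineage D makes.
    """
    config.validate()
    inversion_plan = inversion_plan or []
    ss = np.random.SeedSequence(config.rng_seed)
    s_build, s_I, s_D = ss.spawn(3)
    rng_build = np.random.default_rng(s_build)
    registry = config.get_registry()
    ancestors = [
        build_ancestral_chromosome(config, i, rng_build, registry, name=f"chr{i + 1:02d}")
        for i in range(config.n_chromosomes)
    ]
    genomes: dict[str, list[ChromosomeState]] = {}
    for lineage_idx, (tag, stream) in enumerate((("I", s_I), ("D", s_D))):
        genome = [
            clone_chromosome(
                anc,
                name=f"{anc.name}_{tag}",
                src_base=INSERT_SRC_BASE * (1 + lineage_idx) + i * 1_000_000,
            )
            for i, anc in enumerate(ancestors)
        ]
        if tag == "D":
            for ci, (s, e) in inversion_plan:
                chrom = genome[ci]
                s = snap_to_boundary(chrom, s)
                e = snap_to_boundary(chrom, e)
                if e <= s:
                    raise ConfigError(f"degenerate inversion span on chromosome {ci}")
                apply_inversion(chrom, s, e, config.gene_protection)
        chrom_streams = stream.spawn(config.n_chromosomes)
        for chrom, cs in zip(genome, chrom_streams):
            rng = np.random.default_rng(cs)
            for _ in range(config.n_generations):
                step_generation(chrom, config, rng, registry)
        genomes[tag] = genome
    return DivergentPair(config, registry, ancestors, genomes["I"], genomes["D"])


def surviving_unequal_events(log: Sequence[EventRecord]) -> int:
    """Unequal intrastrand events whose retained solo LTR survives intact.

    Computed purely from the event ledger: an event's solo is destroyed if
    any later deletion removed part of its ancestral-source slice. This is
    the ground truth a sequence-based solo-LTR inventory should recover at
    zero terminus divergence.
    """
    events = list(log)
    count = 0
    for i, ev in enumerate(events):
        if ev.kind != "unequal_intrastrand_deletion":
            continue
        solo_src = ev.detail.get("solo_src")
        if solo_src is None:
            continue
        sid, lo, hi = solo_src
        intact = True
        for later in events[i + 1 :]:
            for r in later.detail.get("removed_src", []):
                if r[0] == sid and r[1] < hi and r[2] > lo:
                    intact = False
                    break
            if not intact:
                break
        if intact:
            count += 1
    return count


def replay_chromosome(ancestor: ChromosomeState, log: Iterable[EventRecord]) -> ChromosomeState:
    """Re-apply a chromosome-local event log to the ancestor.

    Byte-for-byte bookkeeping identity: the result's feature list equals the
    evolved chromosome's. Relocation events (which couple two chromosomes)
    are outside this helper's scope.
    """
    st = clone_chromosome(ancestor)
    for ev in log:
        if ev.kind == "inversion":
            apply_inversion(st, *ev.span, gene_protection=False, record=False)
        elif ev.kind == "illegitimate_deletion":
            delete_span(st, *ev.span, record=False)
        elif ev.kind == "unequal_intrastrand_deletion":
            idx = st.feature_index_at(ev.span[0])
            feat = st.features[idx]
            if (feat.start, feat.end) != ev.span or not feat.is_intact_ltr:
                raise DataError("replay: logged unequal event does not match state")
            convert_to_solo(st, feat, record=False)
        elif ev.kind == "insertion":
            insert_feature(st, ev.span[0], ev.detail["feature"],
                           gene_protection=False, record=False)
        elif ev.kind == "relocation":
            raise DataError("relocation events require genome-level replay")
        else:
            raise DataError(f"unknown event kind {ev.kind!r}")
    st.generation = ancestor.generation
    return st
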