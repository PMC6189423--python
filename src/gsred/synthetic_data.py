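"""Serialization of simulated genome pairs and deterministic test fixtures.

Sequences are synthesised per feature from family template strings: the two
copies of an ortholog share one ancestral sequence (so homology search is
meaningful), TE copies of a family diverge from a family template by a
configurable substitution rate, and LTR terminal repeats are emitted with
zero per-copy divergence by default — young elements carry identical LTRs,
which is what makes the strict 100%-identity solo-LTR criterion exercisable.

Exact whole-genome alignment blocks are derived from feature provenance
rather than from a sequence aligner: every ancestral base surviving in both
lineages is mapped to its current coordinate in each, and maximal runs that
are contiguous in ancestor, genome I and genome D with consistent
orientation become blocks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigError
from .sim_core import (
    ChromosomeState,
    DivergentPair,
    FamilyRegistry,
    Feature,
    RecombinationMap,
    SimConfig,
    clone_chromosome,
    convert_to_solo,
    delete_span,
    simulate_divergent_pair,
    terminal_inversion_plan,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}
_COMP_TABLE = bytes(_COMP.get(i, 78) for i in range(256))


@dataclass
class GenomePairBundle:
    """Paths of one serialized genome pair plus its ground truth."""

    out_dir: Path
    fasta_I: Path
    fasta_D: Path
    gff_I: Path
    gff_D: Path
    marker_map: Path
    alignment_blocks: Path
    truth_events: Path
    ortholog_truth: Path


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------


def _rand_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n, dtype=np.uint8)]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr.copy()
    arr = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return arr


def revcomp(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMP_TABLE).decode()


class SequenceSynthesizer:
    """Deterministic per-copy sequences keyed by the simulation seed.

    Family templates live on stream (seed, 1, family index); ancestral copy
    ``k`` draws its substitutions from stream (seed, 2, k). Slicing a copy
    (for fragmented features) always regenerates the full copy first, so a
    fragment's sequence is exactly the corresponding substring of the intact
    ancestral copy.
    """

    def __init__(
        self,
        pair: DivergentPair,
        divergence: float = 0.02,
        terminus_divergence: float = 0.0,
    ) -> None:
        self.registry = pair.registry
        self.entropy = pair.config.rng_seed
        self.divergence = divergence
        self.terminus_divergence = terminus_divergence
        self._templates: dict[str, np.ndarray] = {}
        self._copies: dict[int, np.ndarray] = {}
        self._src_family: dict[int, Optional[str]] = {}
        self._src_len: dict[int, int] = {}
        self._index_sources(pair)

    def _index_sources(self, pair: DivergentPair) -> None:
        for chrom in pair.ancestors:
            for f in chrom.features:
                if f.src is not None:
                    self._src_family[f.src[0]] = f.family_id
                    self._src_len[f.src[0]] = f.src[2]
        for genome in (pair.genome_I, pair.genome_D):
            for chrom in genome:
                for ev in chrom.log:
                    if ev.kind == "insertion":
                        feat: Feature = ev.detail["feature"]
                        if feat.src is not None:
                            self._src_family[feat.src[0]] = feat.family_id
                            self._src_len[feat.src[0]] = feat.src[2]

    def template(self, family_id: str) -> np.ndarray:
        arr = self._templates.get(family_id)
        if arr is None:
            spec = self.registry[family_id]
            rng = np.random.default_rng(
                np.random.SeedSequence([self.entropy, 1, spec.index])
            )
            if spec.te_class == "LTR" and spec.term_len > 0:
                term = _rand_bases(rng, spec.term_len)
                internal = _rand_bases(rng, spec.length - 2 * spec.term_len)
                arr = np.concatenate([term, internal, term])
            else:
                arr = _rand_bases(rng, spec.length)
            self._templates[family_id] = arr
        return arr

    def copy_array(self, src_id: int) -> np.ndarray:
        arr = self._copies.get(src_id)
        if arr is not None:
            return arr
        fam = self._src_family.get(src_id)
        rng = np.random.default_rng(np.random.SeedSequence([self.entropy, 2, src_id]))
        if fam is None:  # spacer: unrelated random sequence per copy
            arr = _rand_bases(rng, self._src_len[src_id])
        else:
            spec = self.registry[fam]
            tpl = self.template(fam)[: self._src_len[src_id]]
            if spec.te_class == "LTR" and spec.term_len > 0 and tpl.size == spec.length:
                t = spec.term_len
                term5 = _mutate(tpl[:t], self.terminus_divergence, rng)
                internal = _mutate(tpl[t:-t], self.divergence, rng)
                arr = np.concatenate([term5, internal, term5])
            else:
                arr = _mutate(tpl, self.divergence, rng)
        self._copies[src_id] = arr
        return arr

    def feature_sequence(self, feat: Feature) -> str:
        if feat.src is None:
            raise ConfigError("feature without provenance cannot be sequenced")
        sid, lo, hi = feat.src
        arr = self.copy_array(sid)[lo:hi]
        seq = arr.tobytes().decode()
        return revcomp(seq) if feat.flipped else seq

    def chromosome_sequence(self, chrom: ChromosomeState) -> str:
        return "".join(self.feature_sequence(f) for f in chrom.features)


# ---------------------------------------------------------------------------
# Alignment blocks from provenance
# ---------------------------------------------------------------------------


def _provenance_segments(chrom: ChromosomeState, offsets: dict[int, int]):
    segs = []
    for f in chrom.features:
        if f.src is None or f.src[0] not in offsets:
            continue
        sid, lo, hi = f.src
        segs.append((offsets[sid] + lo, offsets[sid] + hi, f.start, f.end, f.flipped))
    segs.sort(key=lambda s: s[0])
    return segs


def _cur_interval(seg, lo, hi):
    a_lo, _a_hi, cs, ce, flip = seg
    off_lo, off_hi = lo - a_lo, hi - a_lo
    if flip:
        return ce - off_hi, ce - off_lo, True
    return cs + off_lo, cs + off_hi, False


def alignment_blocks_for_pair(
    ancestor: ChromosomeState, chrom_i: ChromosomeState, chrom_d: ChromosomeState
) -> pd.DataFrame:
    """Exact aligned blocks between the two descendants of one chromosome."""
    offsets = {f.src[0]: f.start for f in ancestor.features if f.src is not None}
    si = _provenance_segments(chrom_i, offsets)
    sd = _provenance_segments(chrom_d, offsets)
    pieces = []
    i = j = 0
    while i < len(si) and j < len(sd):
        lo = max(si[i][0], sd[j][0])
        hi = min(si[i][1], sd[j][1])
        if lo < hi:
            pieces.append((lo, hi, _cur_interval(si[i], lo, hi), _cur_interval(sd[j], lo, hi)))
        if si[i][1] <= sd[j][1]:
            i += 1
        else:
            j += 1
    blocks = []
    for a_lo, a_hi, (is_, ie_, fi), (ds_, de_, fd) in pieces:
        if blocks:
            b = blocks[-1]
            ok = b["anc_end"] == a_lo and b["_fi"] == fi and b["_fd"] == fd
            if ok:
                ok = (b["start_I"] == ie_) if fi else (b["end_I"] == is_)
            if ok:
                ok = (b["start_D"] == de_) if fd else (b["end_D"] == ds_)
            if ok:
                b["anc_end"] = a_hi
                if fi:
                    b["start_I"] = is_
                else:
                    b["end_I"] = ie_
                if fd:
                    b["start_D"] = ds_
                else:
                    b["end_D"] = de_
                continue
        blocks.append(
            dict(
                chrom_I=chrom_i.name,
                start_I=is_,
                end_I=ie_,
                chrom_D=chrom_d.name,
                start_D=ds_,
                end_D=de_,
                orientation=1 if fi == fd else -1,
                anc_start=a_lo,
                anc_end=a_hi,
                _fi=fi,
                _fd=fd,
            )
        )
    df = pd.DataFrame(
        blocks,
        columns=[
            "chrom_I", "start_I", "end_I", "chrom_D", "start_D", "end_D",
            "orientation", "anc_start", "anc_end", "_fi", "_fd",
        ],
    )
    return df.drop(columns=["_fi", "_fd"])


def mapped_extent(
    ancestor: ChromosomeState, chrom: ChromosomeState, span: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Current-coordinate extent of an ancestral interval in a descendant.

    Returns the min/max current coordinates of all surviving pieces of the
    ancestral span (None if nothing survives) — the truth needed to compare
    detected rearrangement regions against planted ones after sequence has
    been lost or gained.
    """
    offsets = {f.src[0]: f.start for f in ancestor.features if f.src is not None}
    lo = hi = None
    for a_lo, a_hi, cs, ce, _flip in _provenance_segments(chrom, offsets):
        if a_hi <= span[0] or a_lo >= span[1]:
            continue
        cut_lo, cut_hi, _ = _cur_interval((a_lo, a_hi, cs, ce, _flip),
                                          max(a_lo, span[0]), min(a_hi, span[1]))
        lo = cut_lo if lo is None else min(lo, cut_lo)
        hi = cut_hi if hi is None else max(hi, cut_hi)
    return None if lo is None else (lo, hi)


def surviving_bp(
    ancestor: ChromosomeState, chrom: ChromosomeState, span: tuple[int, int]
) -> int:
    """How many bp of an ancestral interval survive in a descendant."""
    offsets = {f.src[0]: f.start for f in ancestor.features if f.src is not None}
    total = 0
    for a_lo, a_hi, _cs, _ce, _flip in _provenance_segments(chrom, offsets):
        total += max(0, min(a_hi, span[1]) - max(a_lo, span[0]))
    return total


def map_ancestral_span(
    pair: DivergentPair, lineage: str, chrom_index: int, span: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """:func:`mapped_extent` addressed through a :class:`DivergentPair`."""
    return mapped_extent(
        pair.ancestors[chrom_index], pair.lineage(lineage)[chrom_index], span
    )


def alignment_blocks(pair: DivergentPair) -> pd.DataFrame:
    frames = [
        alignment_blocks_for_pair(anc, ci, cd)
        for anc, ci, cd in zip(pair.ancestors, pair.genome_I, pair.genome_D)
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------


def sample_marker_map(
    recomb_map: RecombinationMap,
    n_markers: int,
    rng: np.random.Generator,
    chrom: str = "chr01",
    noise_cM: float = 0.0,
) -> pd.DataFrame:
    """Evenly spaced markers with cumulative cM from the c(p) integral.

    With zero noise the last marker's cM equals the map's configured total
    genetic length (up to quadrature error); optional Gaussian noise is
    applied per marker and then forced non-decreasing.
    """
    if n_markers < 2:
        raise ConfigError("need at least 2 markers")
    positions = np.linspace(0, recomb_map.chromosome_length - 1, n_markers).astype(int)
    cm = np.asarray(recomb_map.genetic_position(positions), dtype=float)
    if noise_cM > 0:
        cm = cm + rng.normal(0.0, noise_cM, size=cm.size)
        cm[0] = max(cm[0], 0.0)
        cm = np.maximum.accumulate(np.clip(cm, 0.0, None))
    return pd.DataFrame(
        dict(
            marker_id=[f"{chrom}_m{i:04d}" for i in range(n_markers)],
            chrom=chrom,
            position_bp=positions,
            cM=cm,
        )
    )


# ---------------------------------------------------------------------------
# Bundle writing
# ---------------------------------------------------------------------------


def _event_rows(pair: DivergentPair):
    rows = []
    for tag, genome in (("I", pair.genome_I), ("D", pair.genome_D)):
        for chrom in genome:
            for ev in chrom.log:
                detail = {
                    k: (asdict(v) if isinstance(v, Feature) else v)
                    for k, v in ev.detail.items()
                }
                rows.append(
                    dict(
                        lineage=tag,
                        chrom=chrom.name,
                        generation=ev.generation,
                        kind=ev.kind,
                        start=ev.span[0],
                        end=ev.span[1],
                        length_change=ev.length_change,
                        detail=json.dumps(detail, default=str),
                    )
                )
    return rows


def ortholog_truth(pair: DivergentPair) -> pd.DataFrame:
    """Gene id pairs sharing one ancestral copy (the pairing ground truth)."""
    rows = []
    for ci, cd in zip(pair.genome_I, pair.genome_D):
        by_src = {}
        for chrom, col in ((ci, "gene_I"), (cd, "gene_D")):
            ids = io.feature_ids(chrom)
            for f, fid in zip(chrom.features, ids):
                if f.kind == "gene" and f.src is not None:
                    by_src.setdefault(f.src[0], {})[col] = fid
        for sid in sorted(by_src):
            d = by_src[sid]
            if "gene_I" in d and "gene_D" in d:
                rows.append(dict(src_id=sid, gene_I=d["gene_I"], gene_D=d["gene_D"]))
    return pd.DataFrame(rows, columns=["src_id", "gene_I", "gene_D"])


def write_genome_pair(
    pair: DivergentPair,
    out_dir,
    divergence: float = 0.02,
    terminus_divergence: float = 0.0,
    n_markers: int = 80,
    marker_noise_cM: float = 0.0,
) -> GenomePairBundle:
    """Serialize a simulated pair: FASTA x2, GFF3 x2, marker map, exact
    alignment blocks, event truth, and ortholog truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = SequenceSynthesizer(pair, divergence, terminus_divergence)

    paths = GenomePairBundle(
        out_dir=out,
        fasta_I=out / "genome_I.fasta",
        fasta_D=out / "genome_D.fasta",
        gff_I=out / "genome_I.gff3",
        gff_D=out / "genome_D.gff3",
        marker_map=out / "marker_map.tsv",
        alignment_blocks=out / "alignment_blocks.tsv",
        truth_events=out / "truth_events.tsv",
        ortholog_truth=out / "ortholog_truth.tsv",
    )

    for genome, fasta, gff in (
        (pair.genome_I, paths.fasta_I, paths.gff_I),
        (pair.genome_D, paths.fasta_D, paths.gff_D),
    ):
        io.write_fasta({c.name: synth.chromosome_sequence(c) for c in genome}, fasta)
        io.write_annotation(genome, gff)

    rng = np.random.default_rng(np.random.SeedSequence([pair.config.rng_seed, 3]))
    marker_frames = [
        sample_marker_map(c.recomb, n_markers, rng, chrom=c.name, noise_cM=marker_noise_cM)
        for c in pair.genome_D
    ]
    io.write_tsv(pd.concat(marker_frames, ignore_index=True), paths.marker_map)
    io.write_tsv(alignment_blocks(pair), paths.alignment_blocks)
    io.write_tsv(pd.DataFrame(_event_rows(pair)), paths.truth_events)
    io.write_tsv(ortholog_truth(pair), paths.ortholog_truth)
    return paths


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "tiny-inversion",
    "no-rearrangement",
    "solo-ltr-planted",
    "mechanism-planted",
)


def _planted_mechanism_pair(p_unequal: float = 0.05, n_illegit: int = 190) -> DivergentPair:
    """Well-separated planted deletions with a known unequal fraction.

    Lineage D receives ``n_illegit`` illegitimate deletions (>=1 kb, planted
    wholly inside spacer or non-LTR TE tiles with >=150 bp margins so their
    flanks carry no repeat pair) and converts each intact LTR element to a
    solo LTR with probability ``p_unequal/(1-p_unequal)`` relative odds such
    that unequal events make up ~``p_unequal`` of all planted deletions.
    Events are far apart, so unaligned segments correspond 1:1 to events —
    the clean ground truth for flanking-repeat classification.
    """
    cfg = SimConfig(n_chromosomes=1, chromosome_length=1_200_000,
                    n_generations=0, rng_seed=77)
    rng = np.random.default_rng(np.random.SeedSequence([77, 5]))
    registry = cfg.get_registry()
    ancestor = simulate_divergent_pair(cfg, []).ancestors[0]
    chrom_i = clone_chromosome(ancestor, "chr01_I", src_base=10_000_000)
    chrom_d = clone_chromosome(ancestor, "chr01_D", src_base=20_000_000)

    ops: list[tuple[int, str, tuple]] = []
    last_pos = -10_000
    n_planted = 0
    intact = [(f.start, f.end) for f in chrom_d.intact_ltr_features()]
    n_unequal_target = max(1, int(round(n_illegit * p_unequal / (1 - p_unequal))))
    chosen_elements = [
        span for span in intact if rng.random() < 2 * n_unequal_target / max(len(intact), 1)
    ][:n_unequal_target]
    blocked = [(s - 4_000, e + 4_000) for s, e in chosen_elements]
    for f in chrom_d.features:
        if n_planted >= n_illegit:
            break
        eligible = f.kind == "spacer" or (f.kind == "te" and f.te_class != "LTR")
        if not eligible or f.length < 1_300 or f.start - last_pos < 2_500:
            continue
        if any(f.start < hi and f.end > lo for lo, hi in blocked):
            continue
        max_len = min(f.length - 250, 3_500)
        dlen = int(rng.integers(1_000, max_len + 1))
        start = f.start + 100
        ops.append((start, "del", (start, start + dlen)))
        last_pos = f.end
        n_planted += 1
    for s, _e in chosen_elements:
        ops.append((s, "solo", (s,)))
    for pos, kind, args in sorted(ops, key=lambda o: -o[0]):
        if kind == "del":
            delete_span(chrom_d, *args)
        else:
            feat = chrom_d.features[chrom_d.feature_index_at(args[0])]
            convert_to_solo(chrom_d, feat)
    return DivergentPair(cfg, registry, [ancestor], [chrom_i], [chrom_d])


def _planted_solo_pair() -> DivergentPair:
    """Hand-assembled chromosome with exactly 8 intact LTR elements; three of
    them are converted to solo LTRs in lineage D (the planted truth)."""
    registry = FamilyRegistry()
    registry.add("LTR_famA", "te", 2 * 250 + 2000, te_class="LTR", term_len=250)
    registry.add("LTR_famB", "te", 2 * 300 + 1800, te_class="LTR", term_len=300)
    gene_len = 2000
    feats: list[Feature] = []
    pos = 0
    src = 0

    def push(kind, length, **kw):
        nonlocal pos, src
        f = Feature(kind, pos, pos + length, kw.pop("strand", "+"), **kw)
        f.src = (src, 0, length)
        feats.append(f)
        pos += length
        src += 1

    push("spacer", 1500)
    fams = ["LTR_famA", "LTR_famB"] * 4
    strands = ["+", "-"] * 4
    for k, (fam, strand) in enumerate(zip(fams, strands)):
        spec = registry[fam]
        gfam = f"gP_{k:03d}"
        registry.add(gfam, "gene", gene_len)
        push("gene", gene_len, family_id=gfam, strand="+")
        push(
            "te",
            spec.length,
            family_id=fam,
            te_class="LTR",
            ltr_termini=(spec.term_len, spec.term_len),
            strand=strand,
        )
        push("spacer", 1200)
    L = pos
    recomb = RecombinationMap(L, L // 2)
    ancestor = ChromosomeState("chr01", feats, L, recomb)
    ancestor.validate()
    config = SimConfig(
        n_chromosomes=1, chromosome_length=L, n_generations=0, rng_seed=4242
    )
    chrom_i = clone_chromosome(ancestor, "chr01_I", src_base=10_000_000)
    chrom_d = clone_chromosome(ancestor, "chr01_D", src_base=20_000_000)
    for feat in list(chrom_d.intact_ltr_features())[:3]:
        convert_to_solo(chrom_d, feat)
    return DivergentPair(config, registry, [ancestor], [chrom_i], [chrom_d])


def fixture_pair(name: str) -> DivergentPair:
    """In-memory fixture by registry name (see :data:`FIXTURE_NAMES`)."""
    if name == "tiny-inversion":
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length=400_000, n_generations=800,
            rng_seed=20250917,
        )
        return simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
    if name == "no-rearrangement":
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length=400_000, n_generations=800,
            rng_seed=20250917,
        )
        return simulate_divergent_pair(cfg, [])
    if name == "solo-ltr-planted":
        return _planted_solo_pair()
    if name == "mechanism-planted":
        return _planted_mechanism_pair()
    raise ConfigError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")


def make_fixture(name: str, out_dir) -> GenomePairBundle:
    return write_genome_pair(fixture_pair(name), out_dir)
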