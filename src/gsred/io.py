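"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 emission converts
to 1-based closed and :func:`read_annotation` converts back. Annotations are
exchanged as a flat :class:`pandas.DataFrame` with one row per feature
(kinds: ``gene``, ``te``, ``spacer``, ``ltr_terminus``), which is the
in-memory contract every analysis stage consumes.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .sim_core import ChromosomeState, Feature

ANNOTATION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "kind",
    "feature_id",
    "family_id",
    "te_class",
    "template_id",
    "template_start",
    "template_end",
    "is_solo",
    "parent_id",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Annotation frames
# ---------------------------------------------------------------------------


def _template_id(feat: Feature) -> Optional[str]:
    if feat.family_id is None:
        return None
    if feat.is_solo_ltr:
        return f"tpl:{feat.family_id}:term"
    return f"tpl:{feat.family_id}"


def _template_interval(feat: Feature) -> tuple[Optional[int], Optional[int]]:
    """Which part of its template a TE feature represents (copy-local
    coordinates; a solo LTR spans its terminus template from 0)."""
    if feat.kind != "te" or feat.family_id is None:
        return None, None
    if feat.is_solo_ltr:
        return 0, feat.length
    if feat.src is not None:
        return feat.src[1], feat.src[2]
    return 0, feat.length


def feature_ids(chrom: ChromosomeState) -> list[str]:
    """Deterministic per-chromosome feature identifiers (order-stable)."""
    counters = {"gene": 0, "te": 0, "spacer": 0}
    prefix = {"gene": "g", "te": "t", "spacer": "s"}
    ids = []
    for f in chrom.features:
        n = counters[f.kind]
        counters[f.kind] += 1
        ids.append(f"{chrom.name}.{prefix[f.kind]}{n:05d}")
    return ids


def features_to_frame(chroms: Sequence[ChromosomeState]) -> pd.DataFrame:
    """Flatten chromosome states into the annotation frame contract.

    Intact LTR elements additionally contribute two ``ltr_terminus`` rows
    (template id ``tpl:<family>:term``) so that flanking-repeat analysis sees
    the terminal repeats as repeats in their own right.
    """
    rows = []
    for chrom in chroms:
        ids = feature_ids(chrom)
        for f, fid in zip(chrom.features, ids):
            t_lo, t_hi = _template_interval(f)
            rows.append(
                dict(
                    chrom=chrom.name,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    kind=f.kind,
                    feature_id=fid,
                    family_id=f.family_id,
                    te_class=f.te_class,
                    template_id=_template_id(f),
                    template_start=t_lo,
                    template_end=t_hi,
                    is_solo=f.is_solo_ltr,
                    parent_id=None,
                )
            )
            term = f.terminus_intervals()
            if term is not None:
                for label, (ts, te) in zip(("ltr5", "ltr3"), term):
                    rows.append(
                        dict(
                            chrom=chrom.name,
                            start=ts,
                            end=te,
                            strand=f.strand,
                            kind="ltr_terminus",
                            feature_id=f"{fid}.{label}",
                            family_id=f.family_id,
                            te_class="LTR",
                            template_id=f"tpl:{f.family_id}:term",
                            template_start=0,
                            template_end=te - ts,
                            is_solo=False,
                            parent_id=fid,
                        )
                    )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start", "kind"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_annotation(chroms: Sequence[ChromosomeState], path) -> None:
    """Emit GFF3 (1-based closed): gene/mRNA/CDS skeletons, TE features with
    long_terminal_repeat children for intact elements, and spacer tiles."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chroms:
            fh.write(f"##sequence-region {chrom.name} 1 {chrom.length}\n")
        for chrom in chroms:
            ids = feature_ids(chrom)
            for f, fid in zip(chrom.features, ids):
                s1, e1 = f.start + 1, f.end
                if f.kind == "gene":
                    attrs = f"ID={fid};family_id={f.family_id}"
                    fh.write(_gff_line(chrom.name, "gene", s1, e1, f.strand, attrs))
                    fh.write(
                        _gff_line(chrom.name, "mRNA", s1, e1, f.strand,
                                  f"ID={fid}.m1;Parent={fid}")
                    )
                    fh.write(
                        _gff_line(chrom.name, "CDS", s1, e1, f.strand,
                                  f"ID={fid}.c1;Parent={fid}.m1")
                    )
                elif f.kind == "te":
                    t_lo, t_hi = _template_interval(f)
                    attrs = (
                        f"ID={fid};family_id={f.family_id};te_class={f.te_class};"
                        f"template_id={_template_id(f)}"
                    )
                    if t_lo is not None:
                        attrs += f";template_start={t_lo};template_end={t_hi}"
                    if f.is_solo_ltr:
                        attrs += ";solo=true"
                    fh.write(
                        _gff_line(chrom.name, "transposable_element", s1, e1, f.strand, attrs)
                    )
                    term = f.terminus_intervals()
                    if term is not None:
                        for label, (ts, te) in zip(("ltr5", "ltr3"), term):
                            fh.write(
                                _gff_line(
                                    chrom.name,
                                    "long_terminal_repeat",
                                    ts + 1,
                                    te,
                                    f.strand,
                                    f"ID={fid}.{label};Parent={fid};"
                                    f"template_id=tpl:{f.family_id}:term;"
                                    f"template_start=0;template_end={te - ts}",
                                )
                            )
                else:
                    fh.write(_gff_line(chrom.name, "spacer", s1, e1, f.strand, f"ID={fid}"))


def _gff_line(chrom, ftype, start1, end1, strand, attrs) -> str:
    return f"{chrom}\tgsred\t{ftype}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"


def _validate_gff_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}: malformed GFF3 line {lineno} (expected 9 columns)")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise DataError(f"{path}: non-integer coordinates on line {lineno}") from None
            if start < 1 or end < start:
                raise DataError(f"{path}: bad coordinate range on line {lineno}")


def read_annotation(path, seq_lengths: Optional[dict[str, int]] = None) -> pd.DataFrame:
    """Parse GFF3 into the annotation frame (0-based half-open).

    Unknown feature types are tolerated and ignored by downstream stages.
    Malformed lines raise :class:`DataError` naming the offending line; with
    ``seq_lengths`` supplied, coordinates beyond the sequence end do too.
    """
    import gffutils

    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.all_features(order_by=("seqid", "start")):
        ftype = feat.featuretype
        if ftype in ("mRNA", "CDS"):
            continue
        if seq_lengths is not None and feat.seqid in seq_lengths:
            if feat.end > seq_lengths[feat.seqid]:
                raise DataError(
                    f"{path}: feature {feat.id} ends at {feat.end} beyond "
                    f"{feat.seqid} length {seq_lengths[feat.seqid]}"
                )
        attr = {k: v[0] for k, v in feat.attributes.items()}
        kind = {
            "gene": "gene",
            "transposable_element": "te",
            "long_terminal_repeat": "ltr_terminus",
            "spacer": "spacer",
        }.get(ftype)
        if kind is None:
            continue
        rows.append(
            dict(
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=kind,
                feature_id=attr.get("ID", feat.id),
                family_id=attr.get("family_id"),
                te_class=attr.get("te_class", "LTR" if kind == "ltr_terminus" else None),
                template_id=attr.get("template_id"),
                template_start=(
                    int(attr["template_start"]) if "template_start" in attr else None
                ),
                template_end=(
                    int(attr["template_end"]) if "template_end" in attr else None
                ),
                is_solo=attr.get("solo", "false") == "true",
                parent_id=attr.get("Parent"),
            )
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start", "kind"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV / misc
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_bed(regions: Iterable[tuple[str, int, int]], path) -> None:
    """0-based half-open BED export of region tuples."""
    with open(path, "w") as fh:
        for chrom, s, e in regions:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def chromosome_lengths(chroms: Sequence[ChromosomeState]) -> dict[str, int]:
    return {c.name: c.length for c in chroms}
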