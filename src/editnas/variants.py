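"""Variant-aware target scanning: PAM sites x SNVs -> prediction deltas.

The pipeline scans exonic NGG PAM sites on both strands of a reference
genome, builds the 60 bp model window for each, intersects those windows
with single-nucleotide variants from a VCF, and predicts the six outcome
statistics for the reference and alternative alleles.  Any SNV anywhere in
the 60 bp window is included — the model consumes the whole window, and
known determinants sit well outside the 3 bp PAM.  One variant is
substituted at a time (no haplotypes).

Targets are finally ranked by the mean absolute prediction difference over
all their SNVs and all six statistics, ascending: the least SNV-sensitive
("least variant") targets come first.  Sites with no overlapping SNV score 0
and are flagged rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RefMismatchError, ReferenceError_
from .model import predict
from .outcomes import TASK_NAMES
from .sequences import (LEFT_FLANK, RIGHT_FLANK, WINDOW_LENGTH, TargetSite,
                        extract_window, one_hot, reverse_complement)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide variant on the forward strand (0-based pos)."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantEffectRecord:
    site_id: str
    variant_id: str
    window_position: int  # 1-based position of the SNV within the 60 bp window
    ref_pred: tuple
    alt_pred: tuple

    def __post_init__(self) -> None:
        if not 1 <= self.window_position <= WINDOW_LENGTH:
            raise RefMismatchError(
                f"window_position {self.window_position} outside [1, {WINDOW_LENGTH}]")

    @property
    def abs_diff(self) -> np.ndarray:
        return np.abs(np.asarray(self.ref_pred) - np.asarray(self.alt_pred))

    @property
    def mean_abs_diff(self) -> float:
        return float(self.abs_diff.mean())


def window_span(site: TargetSite) -> tuple[int, int]:
    """Forward-strand genomic half-open interval covered by a site's window."""
    p = site.pam_start_genomic
    if p is None:
        raise ReferenceError_(f"site {site.site_id} has no genomic provenance")
    if site.strand == "+":
        return p - LEFT_FLANK, p + RIGHT_FLANK
    return p - (RIGHT_FLANK - 1), p + LEFT_FLANK + 1


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def scan_pam_sites(genome, exons) -> list[TargetSite]:
    """All NGG PAM sites (both strands) whose first PAM base lies in an exon.

    ``genome`` is a FASTA path or a {chrom: sequence} dict; ``exons`` a BED
    path or DataFrame with chrom/start/end.  Forward hits are positions p
    with GG at p+1..p+2; reverse hits are positions p with CC at p-2..p-1
    (the reverse complement then reads NGG with its first base at p).
    Overlapping sites are all reported.
    """
    if isinstance(genome, dict):
        seqs = {k: v.upper() for k, v in genome.items()}
    else:
        from .sequences import read_fasta

        seqs = read_fasta(genome)
    bed = exons if isinstance(exons, pd.DataFrame) else read_bed(exons)
    sites: list[TargetSite] = []
    for row in bed.itertuples(index=False):
        if row.chrom not in seqs:
            raise ReferenceError_(f"chromosome {row.chrom!r} absent from FASTA")
        seq = seqs[row.chrom]
        for p in range(int(row.start), min(int(row.end), len(seq))):
            if seq[p + 1: p + 3] == "GG":
                sites.append(extract_window(seq, p, "+", chrom=row.chrom))
            if p >= 2 and seq[p - 2: p] == "CC":
                sites.append(extract_window(seq, p, "-", chrom=row.chrom))
    return sites


def read_snvs(vcf_path) -> list[SNV]:
    """Single-nucleotide REF/ALT pairs from a VCF; multi-allelics are split.

    Indels and multi-base alleles are skipped with a log entry.
    """
    from cyvcf2 import VCF

    out: list[SNV] = []
    for v in VCF(str(vcf_path)):
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1:
                logger.info("skipping non-SNV record %s at %s:%d",
                            v.ID or ".", v.CHROM, v.POS)
                continue
            out.append(SNV(variant_id=v.ID or f"{v.CHROM}:{v.POS}:{v.REF}>{alt}",
                           chrom=v.CHROM, pos=v.POS - 1, ref=v.REF.upper(),
                           alt=alt.upper()))
    return out


def window_position_of(site: TargetSite, pos: int) -> int:
    """1-based window position of forward-strand genomic position ``pos``."""
    lo, hi = window_span(site)
    if not lo <= pos < hi:
        raise RefMismatchError(f"position {pos} outside window of {site.site_id}")
    if site.strand == "+":
        return pos - lo + 1
    return hi - 1 - pos + 1


def intersect_variants(sites, variants) -> list[tuple[TargetSite, SNV]]:
    """(site, SNV) pairs where the variant falls inside the 60 bp window.

    ``variants`` is a VCF path or a list of :class:`SNV`.
    """
    if not isinstance(variants, list):
        variants = read_snvs(variants)
    by_chrom: dict[str, list[SNV]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    pairs = []
    for site in sites:
        lo, hi = window_span(site)
        for v in by_chrom.get(site.chrom, []):
            if lo <= v.pos < hi:
                pairs.append((site, v))
    return pairs


def predict_variant_effect(model, site: TargetSite, snv: SNV) -> VariantEffectRecord:
    """Reference vs alternative predictions for one (site, SNV) pair.

    For minus-strand sites the alleles are reverse-complemented into the
    window's frame.  A REF allele that disagrees with the window base is a
    consistency error (likely a coordinate or strand bug) and is raised, not
    silently dropped.
    """
    wp = window_position_of(site, snv.pos)
    ref, alt = snv.ref, snv.alt
    if site.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if site.window[wp - 1] != ref:
        raise RefMismatchError(
            f"{snv.variant_id}: window base {site.window[wp - 1]!r} at position "
            f"{wp} of {site.site_id} != REF {ref!r}")
    alt_window = site.window[: wp - 1] + alt + site.window[wp:]
    X = np.stack([one_hot(site.window), one_hot(alt_window)])
    preds = predict(model, X)
    return VariantEffectRecord(site_id=site.site_id, variant_id=snv.variant_id,
                               window_position=wp,
                               ref_pred=tuple(preds[0]), alt_pred=tuple(preds[1]))


def variant_effect_table(model, sites, variants) -> pd.DataFrame:
    """Per-(site, SNV) effect table; REF mismatches are logged and skipped."""
    rows = []
    for site, snv in intersect_variants(sites, variants):
        try:
            rec = predict_variant_effect(model, site, snv)
        except RefMismatchError as exc:
            logger.warning("%s", exc)
            continue
        row = {"site_id": rec.site_id, "variant_id": rec.variant_id,
               "window_position": rec.window_position}
        for j, task in enumerate(TASK_NAMES):
            row[f"ref_{task}"] = rec.ref_pred[j]
            row[f"alt_{task}"] = rec.alt_pred[j]
            row[f"absdiff_{task}"] = rec.abs_diff[j]
        row["mean_abs_diff"] = rec.mean_abs_diff
        rows.append(row)
    return pd.DataFrame(rows)


def rank_least_variant_targets(records, all_sites=None) -> pd.DataFrame:
    """Rank sites ascending by mean absolute prediction difference.

    ``records`` is a list of :class:`VariantEffectRecord` (or the DataFrame
    from :func:`variant_effect_table`).  The site score averages the
    per-record mean absolute differences over all of the site's SNVs.  Sites
    from ``all_sites`` with no overlapping SNV rank first with score 0 and
    ``no_snv=True``.  Ranking is stable under record reordering.
    """
    if isinstance(records, pd.DataFrame):
        grouped = (records.groupby("site_id")["mean_abs_diff"].agg(["mean", "size"])
                   if len(records) else pd.DataFrame(columns=["mean", "size"]))
        scores = {sid: (row["mean"], int(row["size"]))
                  for sid, row in grouped.iterrows()}
    else:
        agg: dict[str, list[float]] = {}
        for rec in records:
            agg.setdefault(rec.site_id, []).append(rec.mean_abs_diff)
        scores = {sid: (float(np.mean(v)), len(v)) for sid, v in agg.items()}
    rows = [{"site_id": sid, "score": s, "n_snvs": n, "no_snv": False}
            for sid, (s, n) in scores.items()]
    if all_sites is not None:
        covered = set(scores)
        for site in all_sites:
            sid = site.site_id if isinstance(site, TargetSite) else site
            if sid not in covered:
                rows.append({"site_id": sid, "score": 0.0, "n_snvs": 0,
                             "no_snv": True})
    df = pd.DataFrame(rows, columns=["site_id", "score", "n_snvs", "no_snv"])
    return (df.sort_values(["score", "site_id"], kind="stable")
              .reset_index(drop=True))


def large_effect_report(table: pd.DataFrame, task: str = "ins1",
                        min_effect: float = 0.30) -> pd.DataFrame:
    """SNVs whose effect on one statistic (default 1 bp insertion) is large."""
    if table.empty:
        return table
    hits = table[table[f"absdiff_{task}"] >= min_effect]
    return (hits.sort_values(f"absdiff_{task}", ascending=False)
                .reset_index(drop=True))
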