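"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the three kinds of input the pipeline consumes:

1. random 60 bp target windows carrying a valid NGG PAM at the fixed offset;
2. outcome profiles produced by a *planted* sequence-to-outcome rule whose
   dominant determinant is the base 4 bp upstream of the PAM's first base
   (1-based window position 29), mirroring the strongest determinant reported
   for real Cas9 repair data — so interpretation experiments on synthetic
   data double as a qualitative check of that finding;
3. per-target repair-event tables sampled from those profiles, plus a toy
   genome FASTA / exon BED / SNV VCF trio for the variant-effect scan.

The planted rule drives the 1 bp insertion probability; the remaining five
statistics are drawn consistently (``fs1 = ins1 + del1`` holds by
construction because only net lengths {+1, +2, -1, -2, -3} occur, which also
makes profile -> event-class reconstruction exact and invertible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InputError
from .outcomes import OutcomeProfile, RepairEvent
from .sequences import ALPHABET, PAM_OFFSET, WINDOW_LENGTH, TargetSite

#: 0-based window index of the planted determinant: 4 bases upstream of the
#: PAM's first base (index 32), i.e. 1-based window position 29.
PLANTED_POSITION = PAM_OFFSET - 4

#: Event classes the generator emits, as net indel lengths.
EVENT_CLASSES = (1, 2, -1, -2, -3)


@dataclass(frozen=True)
class PlantedRule:
    """Sequence-to-outcome rule with a single dominant positional determinant.

    ``base_effects`` maps the base at ``primary_position`` (0-based; default
    28 = 1-based position 29) to the mean 1 bp insertion probability.  The
    spread of the four effect levels is the signal a model must recover;
    ``noise_sd`` is additive Gaussian observation noise on ins1.

    ``pair_position``/``pair_strength`` optionally add a nonlinear secondary
    effect: ins1 is bumped by ``pair_strength`` when the bases at
    ``pair_position`` and ``primary_position`` are equal.  A purely additive
    rule is fit equally well by almost any architecture in the search space;
    the interaction makes architectures with nonlinear convolution layers
    genuinely better, which is what architecture-search experiments need.
    """

    primary_position: int = PLANTED_POSITION
    base_effects: dict = field(default_factory=lambda: {
        "A": 0.8, "C": 0.55, "G": 0.3, "T": 0.1})
    noise_sd: float = 0.05
    pair_position: int | None = None
    pair_strength: float = 0.0

    def with_interaction(self, position: int = PLANTED_POSITION - 2,
                         strength: float = 0.15) -> "PlantedRule":
        """Copy of the rule with the pairwise interaction enabled."""
        return PlantedRule(self.primary_position, dict(self.base_effects),
                           self.noise_sd, position, strength)


def generate_windows(n: int, seed: int = 0) -> list[TargetSite]:
    """``n`` random 60 bp windows with GG fixed at 1-based positions 34-35."""
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n, WINDOW_LENGTH))
    sites = []
    for i in range(n):
        chars = [ALPHABET[b] for b in draws[i]]
        chars[PAM_OFFSET + 1] = "G"
        chars[PAM_OFFSET + 2] = "G"
        sites.append(TargetSite(window="".join(chars), site_id=f"synth_{i}"))
    return sites


def planted_profiles(windows, rule: PlantedRule = PlantedRule(),
                     seed: int = 0) -> np.ndarray:
    """Vectorised planted profiles, one (6,) row per window.

    ins1 follows the rule (clipped to [0.01, 0.99]); the rest of the
    probability mass is split over the event classes +2, -1, -2, -3 with
    random but invariant-respecting proportions, then summarised into the six
    statistics.
    """
    rng = np.random.default_rng(seed)
    windows = [w.window if isinstance(w, TargetSite) else w for w in windows]
    n = len(windows)
    base = np.array([rule.base_effects[w[rule.primary_position]] for w in windows])
    if rule.pair_position is not None and rule.pair_strength:
        agree = np.array([w[rule.pair_position] == w[rule.primary_position]
                          for w in windows])
        base = base + rule.pair_strength * agree
    ins1 = np.clip(base + rng.normal(0.0, rule.noise_sd, size=n), 0.01, 0.99)
    p_ins2 = rng.uniform(0.0, 0.3, size=n) * (1.0 - ins1)
    del_total = 1.0 - ins1 - p_ins2
    del1 = rng.uniform(0.2, 0.8, size=n) * del_total
    p_del2 = rng.uniform(0.0, 0.8, size=n) * (del_total - del1)
    fs1 = ins1 + del1
    fs2 = p_ins2 + p_del2
    return np.column_stack([ins1, del1, del_total, fs1, fs2, fs1 + fs2])


def planted_profile(window, rule: PlantedRule = PlantedRule(),
                    seed: int = 0) -> OutcomeProfile:
    """Single-window convenience wrapper around :func:`planted_profiles`."""
    return OutcomeProfile.from_array(planted_profiles([window], rule, seed)[0])


def profile_to_class_probs(profile: OutcomeProfile) -> np.ndarray:
    """Invert the six statistics into probabilities over EVENT_CLASSES.

    Only profiles whose mass sits on net lengths {+1, +2, -1, -2, -3} (the
    generator's family) are invertible; anything else is an input error.
    """
    p_ins1 = profile.ins1
    p_ins2 = 1.0 - profile.del_freq - profile.ins1
    p_del1 = profile.del1
    p_del2 = profile.fs2 - p_ins2
    p_del3 = profile.del_freq - profile.del1 - p_del2
    probs = np.array([p_ins1, p_ins2, p_del1, p_del2, p_del3])
    if np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-9:
        raise InputError(f"profile is not representable on {EVENT_CLASSES}: {probs}")
    if abs(profile.fs1 - (profile.ins1 + profile.del1)) > 1e-9:
        raise InputError("fs1 != ins1 + del1: profile outside the generator family")
    return np.clip(probs, 0.0, 1.0)


def simulate_event_table(profile: OutcomeProfile, depth: int,
                         seed: int = 0) -> list[RepairEvent]:
    """Sample ``depth`` indel outcomes from the profile's event classes."""
    if depth < 1:
        raise InputError("depth must be >= 1")
    probs = profile_to_class_probs(profile)
    counts = np.random.default_rng(seed).multinomial(depth, probs / probs.sum())
    return [RepairEvent(net_indel_length=net, count=int(c))
            for net, c in zip(EVENT_CLASSES, counts) if c > 0]


def planted_dataset(n: int, rule: PlantedRule = PlantedRule(), seed: int = 0):
    """Windows, one-hot matrices X (n,4,60) and profile matrix Y (n,6)."""
    from .sequences import encode_batch

    sites = generate_windows(n, seed=seed)
    X = encode_batch(sites)
    Y = planted_profiles(sites, rule, seed=seed + 1)
    return sites, X, Y


# -- toy genome / BED / VCF fixture --------------------------------------------

def _window_span(pam_start: int, strand: str) -> tuple[int, int]:
    from .sequences import LEFT_FLANK, RIGHT_FLANK

    if strand == "+":
        return pam_start - LEFT_FLANK, pam_start + RIGHT_FLANK
    return pam_start - (RIGHT_FLANK - 1), pam_start + LEFT_FLANK + 1


def make_fixture_genome_and_vcf(seed: int, out_dir, length: int = 5000,
                                n_variants: int = 36):
    """Write a toy chromosome FASTA, exon BED and SNV VCF with ground truth.

    Returns a dict of file paths plus the generator's own bookkeeping: PAM
    site counts per strand inside the exons and the exact number of
    (site, SNV) window overlaps, computed by direct position-by-position
    placement while the files are written.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    seq = "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))

    # four exons covering ~60% of the chromosome
    exons = [(200, 1100), (1500, 2600), (3000, 3900), (4200, 4800)]

    fwd_sites, rev_sites = [], []
    for start, end in exons:
        for p in range(start, end):
            if seq[p + 1: p + 3] == "GG":
                fwd_sites.append(p)
            if p >= 2 and seq[p - 2: p] == "CC":
                rev_sites.append(p)
    if len(fwd_sites) < 20 or len(rev_sites) < 20:
        raise InputError("fixture chromosome too sparse in PAM sites; "
                         "increase length")

    spans = ([(_window_span(p, "+"), p, "+") for p in fwd_sites]
             + [(_window_span(p, "-"), p, "-") for p in rev_sites])

    inside = sorted({q for (lo, hi), _, _ in spans
                     for q in range(max(lo, 0), min(hi, length))})
    outside = sorted(set(range(length)) - set(inside))
    n_in = min(2 * n_variants // 3, len(inside))
    n_out = min(n_variants - n_in, len(outside))
    var_pos = sorted(
        list(rng.choice(inside, size=n_in, replace=False))
        + list(rng.choice(outside, size=n_out, replace=False)))

    variants = []
    for i, q in enumerate(var_pos):
        ref = seq[q]
        alt = rng.choice([b for b in ALPHABET if b != ref])
        variants.append((q, f"snv{i:03d}", ref, alt))

    n_pairs = sum(1 for (lo, hi), _, _ in spans for q, *_ in variants
                  if lo <= q < hi)

    fasta_path = out / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, length, 70):
            fh.write(seq[i: i + 70] + "\n")

    bed_path = out / "toy_exons.bed"
    with open(bed_path, "w") as fh:
        for j, (start, end) in enumerate(exons):
            fh.write(f"{chrom}\t{start}\t{end}\texon{j}\n")

    vcf_path = out / "toy_variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for q, vid, ref, alt in variants:
            fh.write(f"{chrom}\t{q + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\n")

    truth = {
        "chrom": chrom,
        "length": length,
        "n_sites_forward": len(fwd_sites),
        "n_sites_reverse": len(rev_sites),
        "n_variants": len(variants),
        "n_pairs": int(n_pairs),
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"fasta": fasta_path, "bed": bed_path, "vcf": vcf_path,
            "truth": truth}
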