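"""Independent brute-force oracles.

Each function re-implements a pipeline computation in the most literal way
possible (per-base enumeration, direct probability arithmetic, exhaustive
counting), deliberately sharing no code with the package internals, so the
optimized implementations can be checked against them.
"""

import itertools
import math

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# intervals: per-base set semantics


def baseset(tuples):
    """Expand (chrom, start, end) tuples into a python set of (chrom, pos)."""
    out = set()
    for chrom, start, end in tuples:
        for p in range(start, end):
            out.add((chrom, p))
    return out


def intervalset_to_tuples(ivs):
    return [(iv.chrom, iv.start, iv.end) for iv in ivs]


def random_interval_tuples(rng, max_pos=300, max_intervals=8, chroms=("chr1", "chr2")):
    n = int(rng.integers(1, max_intervals + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos - 1))
        end = int(rng.integers(start + 1, max_pos + 1))
        out.append((chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# duplicate removal: literal coordinate grouping


def dedup_oracle(pairs):
    """Group by (chrom, outer start, outer end, orientation); keep the
    highest summed-quality pair of each group (first on ties).  Returns the
    set of retained pair names."""
    groups = {}
    for i, p in enumerate(pairs):
        left, right = sorted((p.mate1, p.mate2), key=lambda m: (m.start, m.end))
        key = (
            p.mate1.chrom,
            min(p.mate1.start, p.mate2.start),
            max(p.mate1.end, p.mate2.end),
            (left.strand, right.strand),
        )
        groups.setdefault(key, []).append((i, p))
    keep = set()
    for members in groups.values():
        best_i, best_s = None, -1.0
        for i, p in members:
            s = float(p.mate1.quals.sum() + p.mate2.quals.sum())
            if s > best_s:
                best_i, best_s = i, s
        keep.add(pairs[best_i].name)
    return keep


# ---------------------------------------------------------------------------
# depth: per-position recount


def depth_oracle(mates, target_tuples):
    """{(chrom, pos): depth} over target bases by walking every aligned block."""
    on_target = baseset(target_tuples)
    depth = {key: 0 for key in on_target}
    for m in mates:
        for rs, re_, _ro in m.aligned_blocks():
            for p in range(rs, re_):
                if (m.chrom, p) in depth:
                    depth[(m.chrom, p)] += 1
    return depth


# ---------------------------------------------------------------------------
# genotyping: direct 10-genotype probability arithmetic


GT_SPACE = [(a, a) for a in "ACGT"] + [
    tuple(p) for p in itertools.combinations("ACGT", 2)
]


def genotype_oracle(ref, bases, quals, het=1e-3, hom_alt=5e-4):
    """Posterior over the 10 diploid genotypes, computed observation by
    observation in plain probability space.  Returns (sorted alleles,
    consensus quality, posterior dict keyed by sorted allele pair)."""
    nonref_het_each = het * hom_alt / 3.0
    priors = {}
    for gt in GT_SPACE:
        a1, a2 = gt
        if a1 == a2:
            priors[gt] = (
                1.0 - het - hom_alt - 3 * nonref_het_each if a1 == ref else hom_alt / 3.0
            )
        elif ref in gt:
            priors[gt] = het / 3.0
        else:
            priors[gt] = nonref_het_each

    post = {}
    for gt in GT_SPACE:
        a1, a2 = gt
        like = 1.0
        for b, q in zip(bases, quals):
            e = min(max(10.0 ** (-float(q) / 10.0), 1e-7), 0.75)
            p1 = (1.0 - e) if b == a1 else e / 3.0
            p2 = (1.0 - e) if b == a2 else e / 3.0
            like *= 0.5 * (p1 + p2)
        post[gt] = priors[gt] * like
    z = sum(post.values())
    for gt in post:
        post[gt] /= z

    # argmax with the documented preference order: hom-ref, ref hets, hom
    # alts, non-ref hets, each lexicographic
    def rank(gt):
        a1, a2 = gt
        if a1 == a2 == ref:
            return (0,)
        if a1 != a2 and ref in gt:
            return (1, min(a for a in gt if a != ref))
        if a1 == a2:
            return (2, a1)
        return (3, gt)

    top = max(post.values())
    maxima = [gt for gt in GT_SPACE if post[gt] == top]
    best = min(maxima, key=rank)
    p_err = max(1.0 - post[best], 10.0 ** (-25.5))
    qc = min(-10.0 * math.log10(p_err), 255.0)
    post_sorted = {tuple(sorted(gt)): p for gt, p in post.items()}
    return tuple(sorted(best)), qc, post_sorted


# ---------------------------------------------------------------------------
# concordance: exhaustive counting


def concordance_oracle(calls, gold_entries):
    """Recount every concordance statistic by explicit loops.

    ``gold_entries``: list of (chrom, pos, ref, sorted allele pair).
    Returns a dict of the count-valued statistics.
    """
    gold = {(c, p): (r, gt) for c, p, r, gt in gold_entries}
    call_at = {(c.chrom, c.pos): c for c in calls if (c.chrom, c.pos) in gold}
    counts = dict(
        n_gold=len(gold), n_called=len(call_at), n_disagree=0,
        n_gold_variants=0, n_variants_detected=0,
        n_variant_calls_at_gold=0, n_false_variant_calls=0,
        n_gold_hets=0, n_hets_detected=0, n_het_calls_at_gold=0,
        n_false_het_calls=0, n_het_call_disagreements=0,
    )
    for key, (ref, gt) in gold.items():
        gold_is_variant = any(a != ref for a in gt)
        gold_is_het = gt[0] != gt[1]
        call = call_at.get(key)
        if gold_is_variant:
            counts["n_gold_variants"] += 1
            if call is not None and any(a != call.ref for a in call.alleles):
                counts["n_variants_detected"] += 1
        if gold_is_het:
            counts["n_gold_hets"] += 1
            if call is not None and call.alleles[0] != call.alleles[1]:
                counts["n_hets_detected"] += 1
        if call is None:
            continue
        disagrees = tuple(sorted(call.alleles)) != tuple(sorted(gt))
        if disagrees:
            counts["n_disagree"] += 1
        if any(a != call.ref for a in call.alleles):
            counts["n_variant_calls_at_gold"] += 1
            if not gold_is_variant:
                counts["n_false_variant_calls"] += 1
        if call.alleles[0] != call.alleles[1]:
            counts["n_het_calls_at_gold"] += 1
            if not gold_is_het:
                counts["n_false_het_calls"] += 1
            if disagrees:
                counts["n_het_call_disagreements"] += 1
    return counts


# ---------------------------------------------------------------------------
# coding effect: independent spliced-CDS translation


def coding_effect_oracle(genome_seq, cds_exons, strand, pos, alt):
    """Classify a substitution by rebuilding and translating the whole CDS.

    ``genome_seq``: str of the chromosome; ``cds_exons``: [(start, end)]
    sorted; ``pos`` genomic 0-based; ``alt`` reference-strand base.
    Returns 'synonymous' / 'non-synonymous' / 'non-coding'.
    """
    if not any(s <= pos < e for s, e in cds_exons):
        return "non-coding"
    ref_cds = "".join(genome_seq[s:e] for s, e in cds_exons)
    mutated = list(genome_seq)
    mutated[pos] = alt
    alt_cds = "".join("".join(mutated[s:e]) for s, e in cds_exons)
    if strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    aa_ref = str(Seq(ref_cds).translate())
    aa_alt = str(Seq(alt_cds).translate())
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"
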