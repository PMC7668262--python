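"""Independent brute-force oracles, deliberately naive and separate from the
package's own implementations."""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_hits(query, ref_seq, max_mm):
    """Every end-to-end placement on both strands with <= max_mm mismatches,
    scanning all offsets; N matches nothing, including N."""
    hits = []
    for rank, (strand, q) in enumerate([("+", query), ("-", naive_revcomp(query))]):
        for start in range(len(ref_seq) - len(q) + 1):
            window = ref_seq[start : start + len(q)]
            mm = 0
            for a, b in zip(q, window):
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mm:
                hits.append((strand, start, mm, rank))
    hits.sort(key=lambda h: (h[2], h[1], h[3]))
    return [(s, p, m) for s, p, m, _ in hits]


def naive_utr_alu_counts(gene, repeats, min_overlap_frac=1.0):
    """Interval-overlap census by direct enumeration."""
    n_sense = n_anti = 0
    for rep in repeats:
        if rep.family != "Alu" or rep.chrom != gene.chrom:
            continue
        ov = min(rep.end, gene.utr3_end) - max(rep.start, gene.utr3_start)
        if ov <= 0 or ov < min_overlap_frac * (rep.end - rep.start):
            continue
        if rep.strand == gene.strand:
            n_sense += 1
        else:
            n_anti += 1
    return n_sense, n_anti


def naive_seed_sites(site_7mer, utr):
    """All (possibly overlapping) exact occurrences of a 7-mer."""
    return [i for i in range(len(utr) - 6) if utr[i : i + 7] == site_7mer]
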