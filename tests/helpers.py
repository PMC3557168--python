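"""Shared test-construction helpers."""

from rrlsnp import SiteObservation


def make_site(
    calls,
    quals=None,
    ref="A",
    pos=10,
    contig="c1",
    genotype="GT1",
    depth=None,
    map_quals=None,
):
    """Pileup column with sensible defaults (quality 35 everywhere)."""
    if quals is None:
        quals = [35] * len(calls)
    return SiteObservation(
        genotype_id=genotype,
        contig_id=contig,
        position=pos,
        ref_base=ref,
        depth=len(calls) if depth is None else depth,
        base_calls=calls,
        base_quals=quals,
        map_quals=map_quals,
    )


import itertools
from collections import Counter

import numpy as np

def brute_force_homopolymer(seq, pos, min_run):
    """Oracle: scan every maximal run; flag if any run of length >= min_run
    contains pos or starts/ends immediately next to the run containing pos."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((i, j))  # [i, j)
        i = j
    mine = next(k for k, (a, b) in enumerate(runs) if a <= pos < b)
    neighbours = [k for k in (mine - 1, mine, mine + 1) if 0 <= k < len(runs)]
    return any(runs[k][1] - runs[k][0] >= min_run for k in neighbours)


def brute_force_adjacent(positions, min_gap):
    """Oracle: all-pairs distance check — a position is flagged iff some other
    candidate lies within min_gap bases (gap = |p2-p1|-1 < min_gap)."""
    return {
        p
        for p, q in itertools.permutations(positions, 2)
        if abs(p - q) - 1 < min_gap
    }


def brute_force_discover(observations_by_gt, reference, config):
    """Independent evaluator: every filter applied at every position with no
    staging or shared bookkeeping with the production path."""
    passing = {}
    for gt, observations in observations_by_gt.items():
        depths = [o.depth for o in observations if o.depth >= 1]
        mean = float(np.mean(depths))
        sd = float(np.std(depths))
        raw = []
        for o in observations:
            if o.ref_base not in "ACGT" or not o.base_calls:
                continue
            counts = Counter(b for b in o.base_calls if b != "N")
            if not counts:
                continue
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue
            if top[0][0] == o.ref_base:
                continue
            raw.append((o, top[0][0], top[0][1]))
        cand_positions = sorted((o.contig_id, o.position) for o, _, _ in raw)
        for o, alt, n_top in raw:
            ratio = n_top / len(o.base_calls)
            qual = np.mean([q for b, q in zip(o.base_calls, o.base_quals) if b == alt])
            seq = reference.sequence(o.contig_id)
            ok = (
                o.depth >= config.min_depth
                and o.depth <= mean + 2 * sd
                and round(ratio, 4) >= config.min_consensus_ratio
                and round(float(qual), 4) >= config.min_quality
                and not brute_force_homopolymer(seq, o.position - 1, config.homopolymer_min_run)
                and not any(
                    c == o.contig_id and p != o.position and abs(p - o.position) - 1 < config.min_gap_between_snps
                    for c, p in cand_positions
                )
            )
            if ok:
                passing.setdefault((o.contig_id, o.position), {})[gt] = alt
    return passing


def _random_observations(rng, reference, genotype, n_sites=400, error=0.05):
    obs = []
    for cid, seq in reference.contigs:
        positions = sorted(
            rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False)
        )
        for p in positions:
            depth = int(rng.integers(1, 25))
            if rng.random() < 0.5:
                base = seq[p]
            else:
                base = "ACGT"[int(rng.integers(0, 4))]
            calls = []
            for _ in range(depth):
                if rng.random() < error:
                    calls.append("ACGT"[int(rng.integers(0, 4))])
                else:
                    calls.append(base)
            quals = rng.integers(10, 41, size=depth).tolist()
            obs.append(
                make_site(
                    "".join(calls),
                    quals=quals,
                    ref=seq[p],
                    pos=int(p) + 1,
                    contig=cid,
                    genotype=genotype,
                )
            )
    return obs

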