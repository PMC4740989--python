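"""Independent brute-force oracles used to validate the implementation.

Each oracle is written as a direct, unoptimized transcription of the
definition it checks (per-sample condition enumeration, pairwise-link
closure, naive O(n*m) scanning, exhaustive label permutation) and shares
no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_male_specific(table, classes, cfg) -> list[int]:
    """Row indices passing the segregation filter, by full enumeration."""
    passing = []
    for i in range(table.n_sites):
        ok = True
        for s in table.samples:
            r = int(table.ref_counts[s].iloc[i])
            a = int(table.alt_counts[s].iloc[i])
            depth = r + a
            if depth < cfg.min_depth:
                ok = False
                break
            af = a / depth
            if classes[s] == "female":
                if af > cfg.female_max_af:
                    ok = False
                    break
            else:
                if not (cfg.male_af_lower <= af <= cfg.male_af_upper):
                    ok = False
                    break
        if ok:
            passing.append(i)
    return passing


def oracle_strain_specific(table, classes, cfg) -> dict[str, list[int]]:
    """Leave-one-out filter by treating one male as AF<=female_max at a time."""
    males = [s for s in table.samples if classes[s] == "male_class"]
    out: dict[str, list[int]] = {}
    for left_out in males:
        passing = []
        for i in range(table.n_sites):
            ok = True
            for s in table.samples:
                r = int(table.ref_counts[s].iloc[i])
                a = int(table.alt_counts[s].iloc[i])
                depth = r + a
                if depth < cfg.min_depth:
                    ok = False
                    break
                af = a / depth
                if classes[s] == "female" or s == left_out:
                    if af > cfg.female_max_af:
                        ok = False
                        break
                else:
                    if not (cfg.male_af_lower <= af <= cfg.male_af_upper):
                        ok = False
                        break
            if ok:
                passing.append(i)
        out[left_out] = passing
    return out


def oracle_clusters(positions, max_gap):
    """Connected components of the pairwise within-gap link graph,
    keeping components of size >= 2 (transitive closure reading)."""
    nodes = sorted(set(positions))
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(nodes, 2):
        if a[0] == b[0] and abs(a[1] - b[1]) <= max_gap:
            parent[find(a)] = find(b)
    comps: dict = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return sorted(sorted(c) for c in comps.values() if len(c) >= 2)


def _rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def oracle_locate(probe: str, contigs) -> list[tuple[str, int, str]]:
    """Naive character-by-character scan over every offset and strand."""
    hits = []
    rc = _rc(probe)
    for name, contig in contigs.items():
        contig = contig.upper()
        for start in range(len(contig) - len(probe) + 1):
            window = contig[start : start + len(probe)]
            if all(w == p for w, p in zip(window, probe)):
                hits.append((name, start + 1, "+"))
            if rc != probe and all(w == p for w, p in zip(window, rc)):
                hits.append((name, start + 1, "-"))
    return hits


def oracle_count_hits(reads, probe: str) -> int:
    rc = _rc(probe)
    count = 0
    for read in reads:
        read = read.upper()
        found = False
        for start in range(len(read) - len(probe) + 1):
            window = read[start : start + len(probe)]
            if window == probe or window == rc:
                found = True
                break
        if found:
            count += 1
    return count


def oracle_mann_whitney(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group relabelings.

    Valid for tie-free data; p = 2 * P(U >= max(u, n_a*n_b - u)) under
    the permutation null, capped at 1.
    """
    a, b = list(a), list(b)
    n_a, n_b = len(a), len(b)
    pooled = a + b

    def u_stat(idx_a):
        group_a = [pooled[i] for i in idx_a]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    u_big = max(u_obs, n_a * n_b - u_obs)
    total = 0
    extreme = 0
    for idx_a in combinations(range(n_a + n_b), n_a):
        total += 1
        if u_stat(set(idx_a)) >= u_big:
            extreme += 1
    p = min(1.0, 2.0 * extreme / total)
    return u_obs, p


def oracle_mw_exact_p(u_obs: float, n_a: int, n_b: int) -> float:
    """Exact two-sided Mann-Whitney p for tie-free data via the counting
    recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def count(n, m, u):
        if u < 0:
            return 0
        if n == 0 or m == 0:
            return 1 if u == 0 else 0
        return count(n - 1, m, u - m) + count(n, m - 1, u)

    import math

    total = math.comb(n_a + n_b, n_a)
    u_big = max(u_obs, n_a * n_b - u_obs)
    tail = sum(count(n_a, n_b, u) for u in range(int(np.ceil(u_big)), n_a * n_b + 1))
    return min(1.0, 2.0 * tail / total)


def oracle_distinguishability(panel: dict, read_length: int) -> dict:
    """Exhaustive window enumeration over every (start, end) position pair."""
    positions = sorted({p for v in panel.values() for p in v})
    out = {}
    for copy, variants in panel.items():
        others = [c for c in panel if c != copy]
        ok = not others
        for lo in positions:
            for hi in positions:
                if lo <= hi and hi - lo + 1 <= read_length:
                    window = [p for p in positions if lo <= p <= hi]
                    mine = tuple(panel[copy].get(p) for p in window)
                    if all(
                        tuple(panel[o].get(p) for p in window) != mine for o in others
                    ):
                        ok = True
        out[copy] = "determinable" if ok else "nd"
    return out


def random_variant_table(rng: np.random.Generator, n_samples=None, n_sites=None):
    """A small random VariantTable plus random sex classes."""
    import pandas as pd

    from msy_seg.segregation import VariantTable

    n_samples = n_samples or int(rng.integers(2, 7))
    n_sites = n_sites or int(rng.integers(1, 51))
    samples = [f"S{i}" for i in range(n_samples)]
    n_males = int(rng.integers(2, n_samples + 1)) if n_samples >= 2 else n_samples
    classes = {
        s: ("male_class" if i < n_males else "female") for i, s in enumerate(samples)
    }
    sites = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=n_sites),
            "pos": rng.integers(1, 500, size=n_sites),
            "ref": rng.choice(list("ACGT"), size=n_sites),
            "alt": rng.choice(list("ACGT"), size=n_sites),
        }
    )
    # mixture of extreme and intermediate AFs, including zero-depth cells
    depth = rng.integers(0, 12, size=(n_sites, n_samples))
    alt = np.minimum(depth, rng.integers(0, 13, size=(n_sites, n_samples)) - 1).clip(0)
    zero_alt = rng.random(size=alt.shape) < 0.4
    alt = np.where(zero_alt, 0, alt)
    ref = depth - alt
    table = VariantTable(
        sites,
        pd.DataFrame(ref, columns=samples),
        pd.DataFrame(alt, columns=samples),
    )
    return table, classes
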