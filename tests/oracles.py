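"""Independent brute-force / exact-arithmetic oracles for the statistics.

Everything here is written directly from the defining formulas with plain
loops (and exact rationals where possible), deliberately sharing no code with
the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, permutations

# ---------------------------------------------------------------------------
# masking (complete deletion over the whole alignment)
# ---------------------------------------------------------------------------

def masked_columns(all_seqs: list[str]) -> list[int]:
    L = len(all_seqs[0])
    return [i for i in range(L) if all(s[i] in "ACGT" for s in all_seqs)]


def apply_mask(seqs: list[str], cols: list[int]) -> list[str]:
    return ["".join(s[i] for i in cols) for s in seqs]


# ---------------------------------------------------------------------------
# per-species statistics (on pre-masked sequences)
# ---------------------------------------------------------------------------

def seg_sites(seqs: list[str]) -> int:
    return sum(1 for col in zip(*seqs) if len(set(col)) > 1)


def eta_total(seqs: list[str]) -> int:
    return sum(len(set(col)) - 1 for col in zip(*seqs))


def hap_count(seqs: list[str]) -> int:
    return len(set(seqs))


def hap_diversity(seqs: list[str]) -> float:
    n = len(seqs)
    freqs = [seqs.count(u) / n for u in set(seqs)]
    return n / (n - 1) * (1.0 - sum(f * f for f in freqs))


def pair_diff_total(seqs: list[str]) -> int:
    return sum(
        sum(a != b for a, b in zip(s1, s2)) for s1, s2 in combinations(seqs, 2)
    )


def mean_pair_diff(seqs: list[str]) -> float:
    n = len(seqs)
    return pair_diff_total(seqs) / (n * (n - 1) / 2)


def watterson_theta(seqs: list[str]) -> float:
    n = len(seqs)
    return seg_sites(seqs) / sum(1.0 / i for i in range(1, n))


def tajimas_d(seqs: list[str]) -> float:
    n = len(seqs)
    S = seg_sites(seqs)
    if S == 0 or n < 4:  # variance coefficients vanish identically for n <= 3
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (mean_pair_diff(seqs) - S / a1) / math.sqrt(var)


def singletons(seqs: list[str]) -> int:
    """Mutations carried by exactly one sequence (capped at eta per site)."""
    total = 0
    for col in zip(*seqs):
        bases = set(col)
        ones = sum(1 for b in bases if col.count(b) == 1)
        total += min(ones, len(bases) - 1)
    return total


def fu_li_star(seqs: list[str]) -> tuple[float, float]:
    n = len(seqs)
    eta = eta_total(seqs)
    if n < 4 or eta == 0:  # starred variance vanishes identically for n <= 3
        return math.nan, math.nan
    eta_s = singletons(seqs)
    k = mean_pair_diff(seqs)
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    r = n / (n - 1)
    vds = (r**2 * bn + an**2 * dn - 2 * n * an * (an + 1) / (n - 1) ** 2) / (
        an**2 + bn
    )
    uds = r * (an - r) - vds
    d_star = (r * eta - an * eta_s) / math.sqrt(uds * eta + vds * eta**2)
    vfs = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * an / n**2
        - 8 * bn / n
    ) / (an**2 + bn)
    ufs = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))) / an - vfs
    f_star = (k - (n - 1) / n * eta_s) / math.sqrt(ufs * eta + vfs * eta**2)
    return d_star, f_star


def fu_li_outgroup(seqs: list[str], outgroup: str) -> tuple[float, float]:
    """Outgroup variant: external mutations are derived singletons."""
    n = len(seqs)
    eta = eta_total(seqs)
    if n < 3 or eta == 0:
        return math.nan, math.nan
    eta_e = 0
    for j, og in enumerate(outgroup):
        col = [s[j] for s in seqs]
        for b in set(col):
            if b != og and col.count(b) == 1:
                eta_e += 1
    k = mean_pair_diff(seqs)
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 1.0 if n == 2 else 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vd = 1 + an**2 / (bn + an**2) * (cn - (n + 1) / (n - 1))
    ud = an - 1 - vd
    d = (eta - an * eta_e) / math.sqrt(ud * eta + vd * eta**2)
    vf = (cn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (an**2 + bn)
    uf = (
        1 + (n + 1) / (3 * (n - 1)) - 4 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / an - vf
    f = (k - eta_e) / math.sqrt(uf * eta + vf * eta**2)
    return d, f


def stirling_unsigned(n: int) -> list[int]:
    """Exact |s(n, j)| for j = 0..n."""
    row = [1]
    for m in range(n):
        row = [
            (row[j - 1] if 1 <= j <= m + 1 else 0) + m * (row[j] if j <= m else 0)
            for j in range(m + 2)
        ]
    return row


def fus_fs_exact(seqs: list[str]) -> float:
    """Fu's Fs with exact rational Ewens probabilities (theta = k exactly)."""
    n = len(seqs)
    total = pair_diff_total(seqs)
    if total == 0:
        return math.nan
    theta = Fraction(total, n * (n - 1) // 2)
    h = hap_count(seqs)
    s = stirling_unsigned(n)
    denom = Fraction(1)
    for i in range(n):
        denom *= theta + i
    probs = [Fraction(s[j]) * theta**j / denom for j in range(1, n + 1)]
    sprime = float(sum(probs[h - 1 :]) / sum(probs))
    sprime = min(max(sprime, 1e-12), 1 - 1e-12)
    return math.log(sprime / (1 - sprime))


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def amova_phi_st(groups: list[list[str]]) -> float:
    """Phi_ST from explicit sums of squared (difference-count) distances."""
    seqs = [s for g in groups for s in g]
    N = len(seqs)
    P = len(groups)

    def d(s1, s2):
        return sum(a != b for a, b in zip(s1, s2))

    ssd_total = sum(d(a, b) for a, b in combinations(seqs, 2)) / N
    ssd_within = sum(
        sum(d(a, b) for a, b in combinations(g, 2)) / len(g) for g in groups
    )
    sigma_w = ssd_within / (N - P)
    n_c = (N - sum(len(g) ** 2 for g in groups) / N) / (P - 1)
    sigma_a = ((ssd_total - ssd_within) / (P - 1) - sigma_w) / n_c
    if sigma_a + sigma_w == 0:
        return math.nan
    return sigma_a / (sigma_a + sigma_w)


def shared_fixed_counts(ga: list[str], gb: list[str]) -> tuple[int, int, int, int]:
    s1 = s2 = sp = fp = 0
    for col_a, col_b in zip(zip(*ga), zip(*gb)):
        pa, pb = len(set(col_a)) > 1, len(set(col_b)) > 1
        if pa and pb:
            sp += 1
        elif pa:
            s1 += 1
        elif pb:
            s2 += 1
        elif col_a[0] != col_b[0]:
            fp += 1
    return s1, s2, sp, fp


# --- independent Nei-Gojobori ---------------------------------------------

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def ng_syn_sites(codon: str) -> float:
    aa = _CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODE[alt] == "*":
                continue
            if _CODE[alt] == aa:
                syn += 1
        total += syn / 3
    return total


def ng_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*":
                blocked = True
            if _CODE[cur] == "*" or _CODE[nxt] == "*":
                nd += 1
            elif _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    use = [(s, n) for s, n, b in results if not b] or [(s, n) for s, n, _ in results]
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def ng_ka_ks(pairs: list[tuple[str, str]]) -> tuple[float, float]:
    """Pooled Nei-Gojobori Ka, Ks (JC-corrected) over codon-sequence pairs."""
    S = N = sd = nd = 0.0
    for s1, s2 in pairs:
        for i in range(0, len(s1) - 2, 3):
            c1, c2 = s1[i : i + 3], s2[i : i + 3]
            if _CODE[c1] == "*" or _CODE[c2] == "*":
                continue
            s_sites = (ng_syn_sites(c1) + ng_syn_sites(c2)) / 2
            S += s_sites
            N += 3 - s_sites
            a, b = ng_path_diffs(c1, c2)
            sd += a
            nd += b

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(nd / N if N else 0.0), jc(sd / S if S else 0.0)
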