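"""Per-species, per-pair and dataset-level summary statistics.

Implements the classical multilocus descriptors (segregating sites, haplotype
diversity, nucleotide diversity, Watterson's theta), the neutrality tests
(Tajima's D, Fu & Li's D/F in starred and outgroup variants, Fu's Fs via the
Ewens sampling formula), distance-based AMOVA Phi_ST with a permutation test,
Nei-Gojobori Ka/Ks, shared/fixed polymorphism counts with the parallel-mutation
expectation, and the ordered multilocus statistic vector used for ABC.

All site-based statistics operate on *retained* sites: columns containing N or
'-' in any sequence are excluded (complete deletion), so S, pi and Phi_ST are
computed on a single consistent mask per locus.

Undefined statistics (e.g. Tajima's D of a monomorphic sample) are returned as
NaN, never silently 0; the only place NaNs are replaced is the documented
imputation step when assembling a complete ABC statistic vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .data_model import LocusAlignment, MultilocusDataset, haplotype_spectrum

__all__ = [
    "SpeciesLocusStats",
    "PairLocusStats",
    "StatConfig",
    "StatVector",
    "species_locus_stats",
    "tajimas_d",
    "fu_li",
    "fus_fs",
    "phi_st",
    "ka_ks",
    "shared_fixed",
    "expected_shared_parallel",
    "stat_vector",
    "locus_stat_block",
    "summary_report",
]

_FS_CLIP = 1e-12  # saturation guard on the Ewens tail probability


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------

def harmonic(m: int) -> float:
    """a_m = sum_{i=1..m} 1/i."""
    return float(sum(1.0 / i for i in range(1, m + 1)))


def harmonic2(m: int) -> float:
    """b_m = sum_{i=1..m} 1/i^2."""
    return float(sum(1.0 / i**2 for i in range(1, m + 1)))


@lru_cache(maxsize=None)
def log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, j)| for j = 0..n (unsigned Stirling numbers, first kind).

    Built with exact integer arithmetic, then converted to logs; for the
    sample sizes used here the integers stay well inside float range.
    """
    row = [1]  # n = 0
    for m in range(n):
        # |s(m+1, j)| = |s(m, j-1)| + m * |s(m, j)|
        nxt = [0] * (m + 2)
        for j in range(m + 2):
            nxt[j] = (row[j - 1] if j >= 1 and j - 1 <= m else 0) + m * (
                row[j] if j <= m else 0
            )
        row = nxt
    return tuple(-math.inf if v == 0 else math.log(v) for v in row)


def _species_matrix(al: LocusAlignment, species: str) -> np.ndarray:
    """Retained-site base matrix (values 0..3) for one species."""
    mat = al.matrix()
    mask = (mat < 4).all(axis=0)
    return mat[np.ix_(al.indices_for(species), np.flatnonzero(mask))]


def _allele_counts(mat: np.ndarray) -> np.ndarray:
    """(n_sites, 4) counts of A,C,G,T down the columns of ``mat``."""
    counts = np.zeros((mat.shape[1], 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    return counts


def _pairdiff_sum(counts: np.ndarray, n: int) -> float:
    """Sum over sites of the number of sequence pairs differing at that site."""
    return float(((n * n - (counts**2).sum(axis=1)) / 2.0).sum())


# ---------------------------------------------------------------------------
# per-species statistics
# ---------------------------------------------------------------------------

@dataclass
class SpeciesLocusStats:
    """Table-1-style descriptors for one species at one locus."""

    species: str
    locus_id: str
    n: int
    retained_length: int
    S: int
    eta: int
    h: int
    hd: float
    pi: float
    k: float
    theta_w: float        # per locus
    theta_w_site: float   # per site
    d_taj: float
    d_fl: float
    f_fl: float
    fs: float
    fs_clipped: bool = False


def _matrix_species_stats(mat: np.ndarray) -> dict:
    """Core statistics from a retained-site base matrix (one species)."""
    n, L = mat.shape
    counts = _allele_counts(mat)
    n_alleles = (counts > 0).sum(axis=1)
    S = int((n_alleles > 1).sum())
    eta = int((n_alleles - 1).sum())
    # haplotypes: exact row identity
    if L:
        _, hap_counts = np.unique(mat, axis=0, return_counts=True)
    else:
        hap_counts = np.array([n])
    h = len(hap_counts)
    hd = (
        float(n / (n - 1) * (1.0 - ((hap_counts / n) ** 2).sum())) if n > 1 else math.nan
    )
    npairs = n * (n - 1) / 2.0
    k = _pairdiff_sum(counts, n) / npairs if npairs else math.nan
    return {
        "n": n,
        "L": L,
        "S": S,
        "eta": eta,
        "h": h,
        "hd": hd,
        "k": k,
        "counts": counts,
        "n_alleles": n_alleles,
    }


def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of Tajima's variance normalisation for sample size n."""
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _tajimas_d_from(S: int, k: float, n: int) -> float:
    if S < 1 or n < 4:
        # the variance coefficients vanish identically for n <= 3
        return math.nan
    a1, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (k - S / a1) / math.sqrt(var)


def tajimas_d(al: LocusAlignment, species: str) -> float:
    """Tajima's D; NaN when the sample is monomorphic."""
    st = _matrix_species_stats(_species_matrix(al, species))
    return _tajimas_d_from(st["S"], st["k"], st["n"])


def _fs_from(k: float, h: int, n: int) -> tuple[float, bool]:
    """Fu's Fs from mean pairwise differences and haplotype count.

    S' = P(K >= h | theta = k) under the Ewens sampling formula, evaluated in
    log space with unsigned Stirling numbers; Fs = ln(S'/(1-S')).
    """
    if not (k > 0) or n < 2:
        return math.nan, False
    logs = log_stirling_row(n)
    logtheta = math.log(k)
    log_rising = sum(math.log(k + i) for i in range(n))
    terms = [logs[j] + j * logtheta - log_rising for j in range(1, n + 1)]
    mx = max(terms)
    total = sum(math.exp(t - mx) for t in terms)
    tail = sum(math.exp(t - mx) for t in terms[h - 1 :])
    sprime = tail / total
    clipped = not (_FS_CLIP <= sprime <= 1.0 - _FS_CLIP)
    sprime = min(max(sprime, _FS_CLIP), 1.0 - _FS_CLIP)
    return math.log(sprime / (1.0 - sprime)), clipped


def fus_fs(al: LocusAlignment, species: str) -> float:
    """Fu's Fs; NaN when k = 0 (no pairwise differences)."""
    st = _matrix_species_stats(_species_matrix(al, species))
    return _fs_from(st["k"], st["h"], st["n"])[0]


def _fu_li_constants(n: int) -> dict:
    an = harmonic(n - 1)
    bn = harmonic2(n - 1)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 1.0 if n == 2 else 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    # outgroup variants
    vD = 1.0 + an**2 / (bn + an**2) * (cn - (n + 1) / (n - 1))
    uD = an - 1.0 - vD
    vF = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (
        an**2 + bn
    )
    uF = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (an1 - 2.0 * n / (n + 1))
    ) / an - vF
    # starred variants (no outgroup), Fu & Li 1993 with the standard correction
    if n > 2:
        dn = (
            cn
            + (n - 2) / (n - 1) ** 2
            + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
        )
    else:
        dn = math.nan
    r = n / (n - 1.0)
    vDs = (r**2 * bn + an**2 * dn - 2 * (n * an * (an + 1)) / (n - 1) ** 2) / (
        an**2 + bn
    )
    uDs = r * (an - r) - vDs
    vFs = (
        (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
        + (2.0 * (n - 1) * an) / n**2
        - 8.0 * bn / n
    ) / (an**2 + bn)
    uFs = ((4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1) * an1) / (3.0 * n * (n - 1))) / an - vFs
    return dict(an=an, vD=vD, uD=uD, vF=vF, uF=uF, vDs=vDs, uDs=uDs, vFs=vFs, uFs=uFs)


def fu_li(
    al: LocusAlignment,
    species: str,
    mode: str = "starred",
    outgroup: str | None = None,
) -> tuple[float, float]:
    """Fu & Li's (D, F); starred uses within-sample singletons, outgroup mode
    polarises external-branch mutations by parsimony against an outgroup
    sequence (same length as the alignment)."""
    if mode not in ("starred", "outgroup"):
        raise ValueError(f"unknown mode {mode!r}")
    mat_full = al.matrix()
    mask = (mat_full < 4).all(axis=0)
    if mode == "outgroup":
        if outgroup is None:
            raise ValueError("outgroup mode requires an outgroup sequence")
        if len(outgroup) != al.length:
            raise ValueError("outgroup sequence length must match the alignment")
        og = np.frombuffer(outgroup.upper().encode(), dtype=np.uint8)
        lut = np.full(256, 4, dtype=np.int8)
        for i, c in enumerate("ACGTN-"):
            lut[ord(c)] = i
        og_codes = lut[og.astype(np.intp)]
        mask = mask & (og_codes < 4)
        og_codes = og_codes[mask]
    idx = al.indices_for(species)
    mat = mat_full[np.ix_(idx, np.flatnonzero(mask))]
    st = _matrix_species_stats(mat)
    n, eta, k = st["n"], st["eta"], st["k"]
    # starred variance coefficients vanish identically for n <= 3
    if eta < 1 or n < (4 if mode == "starred" else 3):
        return math.nan, math.nan
    c = _fu_li_constants(n)
    counts = st["counts"]
    if mode == "starred":
        singles = np.minimum((counts == 1).sum(axis=1), st["n_alleles"] - 1)
        eta_s = int(singles.sum())
        num_d = (n / (n - 1.0)) * eta - c["an"] * eta_s
        den_d = math.sqrt(c["uDs"] * eta + c["vDs"] * eta**2)
        num_f = k - ((n - 1.0) / n) * eta_s
        den_f = math.sqrt(c["uFs"] * eta + c["vFs"] * eta**2)
    else:
        derived_single = (counts == 1) & (
            np.arange(4)[None, :] != og_codes[:, None]
        )
        eta_e = int(derived_single.sum())
        num_d = eta - c["an"] * eta_e
        den_d = math.sqrt(c["uD"] * eta + c["vD"] * eta**2)
        num_f = k - eta_e
        den_f = math.sqrt(c["uF"] * eta + c["vF"] * eta**2)
    d = num_d / den_d if den_d > 0 else math.nan
    f = num_f / den_f if den_f > 0 else math.nan
    return d, f


def species_locus_stats(al: LocusAlignment, species: str) -> SpeciesLocusStats:
    """All Table-1-style statistics for one species at one locus."""
    mat = _species_matrix(al, species)
    if mat.shape[0] < 2:
        raise ValueError(
            f"{al.locus_id}/{species}: need >= 2 sequences, have {mat.shape[0]}"
        )
    st = _matrix_species_stats(mat)
    n, L, S, k = st["n"], st["L"], st["S"], st["k"]
    a1 = harmonic(n - 1)
    theta_w = S / a1
    fs, clipped = _fs_from(k, st["h"], n)
    d_fl, f_fl = fu_li(al, species, mode="starred")
    return SpeciesLocusStats(
        species=species,
        locus_id=al.locus_id,
        n=n,
        retained_length=L,
        S=S,
        eta=st["eta"],
        h=st["h"],
        hd=st["hd"],
        pi=k / L if L else math.nan,
        k=k,
        theta_w=theta_w,
        theta_w_site=theta_w / L if L else math.nan,
        d_taj=_tajimas_d_from(S, k, n),
        d_fl=d_fl,
        f_fl=f_fl,
        fs=fs,
        fs_clipped=clipped,
    )


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def _amova_phi(d: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Phi_ST from a pairwise-difference matrix and group index arrays."""
    N = d.shape[0]
    P = len(groups)
    ssd_t = d[np.triu_indices(N, 1)].sum() / N
    ssd_w = 0.0
    for g in groups:
        sub = d[np.ix_(g, g)]
        ssd_w += sub[np.triu_indices(len(g), 1)].sum() / len(g)
    ssd_a = ssd_t - ssd_w
    sigma_w = ssd_w / (N - P)
    n_prime = (N - sum(len(g) ** 2 for g in groups) / N) / (P - 1)
    sigma_a = (ssd_a / (P - 1) - sigma_w) / n_prime
    tot = sigma_a + sigma_w
    if tot == 0:
        return math.nan
    return sigma_a / tot


def phi_st(
    al: LocusAlignment,
    species_a: str | None = None,
    species_b: str | None = None,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pairwise (or, with no species given, overall) AMOVA Phi_ST.

    The permutation p-value is the proportion of label permutations with
    Phi_ST >= observed, counting the observed arrangement in both numerator
    and denominator; ``n_perm = 0`` returns ``p = nan``.
    """
    if (species_a is None) != (species_b is None):
        raise ValueError("give both species or neither")
    if species_a is not None:
        al = al.subset([species_a, species_b])
        group_names = [species_a, species_b]
    else:
        group_names = al.species
    if len(group_names) < 2:
        raise ValueError("Phi_ST needs at least two groups")
    mat = al.matrix()
    keep = np.flatnonzero((mat < 4).all(axis=0))
    mat = mat[:, keep]
    labels = np.array([group_names.index(s) for s in al.species_labels])
    for g in range(len(group_names)):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {group_names[g]!r} has < 2 sequences")
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    groups = [np.flatnonzero(labels == g) for g in range(len(group_names))]
    obs = _amova_phi(d, groups)
    if n_perm <= 0 or math.isnan(obs):
        return obs, math.nan
    rng = rng or np.random.default_rng()
    n = len(labels)
    hits = 1  # the observed arrangement
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pg = [perm[g] for g in groups]
        if _amova_phi(d, pg) >= obs - 1e-12:
            hits += 1
    return obs, hits / (n_perm + 1)


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD_TABLE.stop_codons)
_BASES = "ACGT"


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (Nei-Gojobori counting)."""
    if codon in _STOPS or any(c not in _BASES for c in codon):
        return math.nan
    aa = _STANDARD_TABLE.forward_table[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue  # changes to stops are excluded from site counting
            if _STANDARD_TABLE.forward_table[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all mutational pathways; pathways through stop codons are discarded
    unless every pathway is blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if cur in _STOPS or nxt in _STOPS:
                # amino-acid comparison undefined through a stop; treat the
                # step as nonsynonymous
                nd += 1
            elif _STANDARD_TABLE.forward_table[cur] == _STANDARD_TABLE.forward_table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    n_codons: int


def ka_ks(
    al: LocusAlignment, species_a: str, species_b: str, frame: int = 0
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks between two species' samples, Jukes-Cantor corrected.

    Codons are read from ``frame`` in the original coordinates; codons with
    any masked site are skipped.  Per-site proportions are averaged over all
    between-species sequence pairs before correction.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    mat = al.matrix()
    mask = (mat < 4).all(axis=0)
    codon_starts = [
        p
        for p in range(frame, al.length - 2, 3)
        if mask[p] and mask[p + 1] and mask[p + 2]
    ]
    if not codon_starts:
        raise ValueError("no complete retained codons in this frame")
    ia = al.indices_for(species_a)
    ib = al.indices_for(species_b)
    # consensus stop check (majority base per retained codon site)
    for p in codon_starts:
        cons = "".join(
            _BASES[np.bincount(mat[:, p + o], minlength=4).argmax()] for o in range(3)
        )
        if cons in _STOPS:
            raise ValueError(f"internal stop codon in consensus at site {p + 1}")
    ssum = nsum = sdsum = ndsum = 0.0
    npairs = 0
    for i in ia:
        for j in ib:
            s_sites = n_sites = sd = nd = 0.0
            for p in codon_starts:
                c1 = "".join(_BASES[mat[i, p + o]] for o in range(3))
                c2 = "".join(_BASES[mat[j, p + o]] for o in range(3))
                if c1 in _STOPS or c2 in _STOPS:
                    continue
                s1 = _syn_sites(c1)
                s2 = _syn_sites(c2)
                s_sites += (s1 + s2) / 2.0
                n_sites += 3.0 - (s1 + s2) / 2.0
                a, b = _codon_path_counts(c1, c2)
                sd += a
                nd += b
            if s_sites > 0 or n_sites > 0:
                ssum += s_sites
                nsum += n_sites
                sdsum += sd
                ndsum += nd
                npairs += 1
    if npairs == 0:
        raise ValueError("no comparable codon pairs")
    ps = sdsum / ssum if ssum > 0 else 0.0
    pn = ndsum / nsum if nsum > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else math.nan
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, n_codons=len(codon_starts))


def shared_fixed(
    al: LocusAlignment, species_a: str, species_b: str
) -> tuple[int, int, int, int]:
    """(s1, s2, Sp, Fp): private polymorphisms, shared polymorphisms and fixed
    differences between two species, per retained site."""
    mat = al.matrix()
    mask = np.flatnonzero((mat < 4).all(axis=0))
    A = mat[np.ix_(al.indices_for(species_a), mask)]
    B = mat[np.ix_(al.indices_for(species_b), mask)]
    poly_a = (A != A[0]).any(axis=0)
    poly_b = (B != B[0]).any(axis=0)
    s1 = int((poly_a & ~poly_b).sum())
    s2 = int((poly_b & ~poly_a).sum())
    sp = int((poly_a & poly_b).sum())
    fp = int((~poly_a & ~poly_b & (A[0] != B[0])).sum())
    return s1, s2, sp, fp


def expected_shared_parallel(s1: int, s2: int, L: int) -> float:
    """Expected shared polymorphic sites if the two species' mutations hit
    sites uniformly and independently: E[Sp] = s1*s2/L."""
    if L <= 0:
        raise ValueError("retained length must be positive")
    return s1 * s2 / L


@dataclass
class PairLocusStats:
    """Table-2/3-style pairwise descriptors for one locus."""

    species_a: str
    species_b: str
    locus_id: str
    s1: int
    s2: int
    sp: int
    fp: int
    e_sp: float
    ka: float
    ks: float
    ka_ks: float
    phi_st: float
    phi_p: float
    dxy: float  # mean between-species pairwise differences per site


def pair_locus_stats(
    al: LocusAlignment,
    species_a: str,
    species_b: str,
    n_perm: int = 0,
    frame: int | None = 0,
    rng: np.random.Generator | None = None,
) -> PairLocusStats:
    s1, s2, sp, fp = shared_fixed(al, species_a, species_b)
    L = al.retained_length()
    phi, p = phi_st(al, species_a, species_b, n_perm=n_perm, rng=rng)
    mat = al.matrix()
    keep = np.flatnonzero((mat < 4).all(axis=0))
    A = mat[np.ix_(al.indices_for(species_a), keep)]
    B = mat[np.ix_(al.indices_for(species_b), keep)]
    dxy_count = float((A[:, None, :] != B[None, :, :]).sum(axis=2).mean())
    try:
        kk = ka_ks(al, species_a, species_b, frame=frame) if frame is not None else None
    except ValueError:
        kk = None
    return PairLocusStats(
        species_a=species_a,
        species_b=species_b,
        locus_id=al.locus_id,
        s1=s1,
        s2=s2,
        sp=sp,
        fp=fp,
        e_sp=expected_shared_parallel(s1, s2, L) if L else math.nan,
        ka=kk.ka if kk else math.nan,
        ks=kk.ks if kk else math.nan,
        ka_ks=kk.ratio if kk else math.nan,
        phi_st=phi,
        phi_p=p,
        dxy=dxy_count / L if L else math.nan,
    )


# ---------------------------------------------------------------------------
# the ABC statistic vector
# ---------------------------------------------------------------------------

PER_SPECIES_STATS = ("S", "h", "k", "tajd", "fs")


@dataclass
class StatConfig:
    """Layout of the multilocus ABC statistic vector.

    The full layout has, for three species, 36 entries: per-species
    across-locus means of {S, h, k, Tajima's D, Fu's Fs} (15), per-pair
    absolute deviations of those means (15), per-pair mean Phi_ST (3) and
    per-pair mean between-species pairwise differences (3).  ``names``
    restricts the vector to a subset (e.g. a correlation-pruned 31-entry
    layout) while preserving order.
    """

    names: tuple[str, ...] | None = None

    def layout(self, species: Sequence[str]) -> list[str]:
        full = []
        for sp in species:
            full += [f"{st}_{sp}" for st in PER_SPECIES_STATS]
        pairs = [
            (species[i], species[j])
            for i in range(len(species))
            for j in range(i + 1, len(species))
        ]
        for a, b in pairs:
            full += [f"d{st}_{a}_{b}" for st in PER_SPECIES_STATS]
        full += [f"phist_{a}_{b}" for a, b in pairs]
        full += [f"dxy_{a}_{b}" for a, b in pairs]
        if self.names is None:
            return full
        missing = set(self.names) - set(full)
        if missing:
            raise ValueError(f"unknown statistic names: {sorted(missing)}")
        return [n for n in full if n in set(self.names)]


@dataclass
class StatVector:
    names: list[str]
    values: np.ndarray
    n_imputed: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"names": self.names, "values": self.values.tolist(), "n_imputed": self.n_imputed}
        )


def locus_stat_block(al: LocusAlignment, species: Sequence[str]) -> np.ndarray:
    """Raw per-locus block feeding the ABC vector.

    Layout (3 species): [S, h, k, D, Fs] per species (15), then per pair
    Phi_ST (3), then per pair mean between-species pairwise differences,
    counted per locus (3).  Undefined entries are NaN.
    """
    ns = len(species)
    pairs = [(i, j) for i in range(ns) for j in range(i + 1, ns)]
    out = np.full(5 * ns + 2 * len(pairs), np.nan)
    mat = al.matrix()
    keep = np.flatnonzero((mat < 4).all(axis=0))
    mats = [mat[np.ix_(al.indices_for(sp), keep)] for sp in species]
    for si, m in enumerate(mats):
        st = _matrix_species_stats(m)
        out[5 * si : 5 * si + 3] = st["S"], st["h"], st["k"]
        out[5 * si + 3] = _tajimas_d_from(st["S"], st["k"], st["n"])
        out[5 * si + 4] = _fs_from(st["k"], st["h"], st["n"])[0]
    for pi, (i, j) in enumerate(pairs):
        A, B = mats[i], mats[j]
        na, nb = A.shape[0], B.shape[0]
        ca = _allele_counts(A)
        cb = _allele_counts(B)
        cross = float((na * nb - (ca * cb).sum(axis=1)).sum())
        out[5 * ns + len(pairs) + pi] = cross / (na * nb)
        sum_a = _pairdiff_sum(ca, na)
        sum_b = _pairdiff_sum(cb, nb)
        N = na + nb
        ssd_w = sum_a / na + sum_b / nb
        ssd_t = (sum_a + sum_b + cross) / N
        sigma_w = (ssd_w) / (N - 2)
        n_prime = (N - (na * na + nb * nb) / N)
        sigma_a = ((ssd_t - ssd_w) - sigma_w) / n_prime
        tot = sigma_a + sigma_w
        out[5 * ns + pi] = math.nan if tot == 0 else sigma_a / tot
    return out


def assemble_vector(
    blocks: np.ndarray, species: Sequence[str], cfg: StatConfig | None = None
) -> StatVector:
    """Across-locus aggregation of per-locus blocks into the ordered vector.

    Undefined per-locus entries are imputed to 0 (the neutral-expectation
    centre) before averaging; the imputation count is recorded.
    """
    cfg = cfg or StatConfig()
    ns = len(species)
    pairs = [(i, j) for i in range(ns) for j in range(i + 1, ns)]
    n_imputed = int(np.isnan(blocks).sum())
    filled = np.nan_to_num(blocks, nan=0.0)
    means = filled.mean(axis=0)
    values: dict[str, float] = {}
    for si, sp in enumerate(species):
        for k_, st in enumerate(PER_SPECIES_STATS):
            values[f"{st}_{sp}"] = means[5 * si + k_]
    for pi, (i, j) in enumerate(pairs):
        a, b = species[i], species[j]
        for k_, st in enumerate(PER_SPECIES_STATS):
            values[f"d{st}_{a}_{b}"] = abs(means[5 * i + k_] - means[5 * j + k_])
        values[f"phist_{a}_{b}"] = means[5 * ns + pi]
        values[f"dxy_{a}_{b}"] = means[5 * ns + len(pairs) + pi]
    names = cfg.layout(species)
    return StatVector(
        names=names,
        values=np.array([values[n] for n in names]),
        n_imputed=n_imputed,
    )


def stat_vector(ds: MultilocusDataset, cfg: StatConfig | None = None) -> StatVector:
    """The ordered multilocus summary-statistic vector of a dataset."""
    blocks = np.stack([locus_stat_block(al, ds.species) for al in ds.loci])
    return assemble_vector(blocks, ds.species, cfg)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def summary_report(
    ds: MultilocusDataset,
    n_perm: int = 10_000,
    frame: int | None = 0,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Tables 1/2/3-style report: per-locus rows plus across-locus mean +- SE.

    Standard error is the across-locus sample SD divided by sqrt(#loci);
    permutation p-values are flagged at 0.05 (*) and 0.01 (**).
    """
    rng = np.random.default_rng(seed)
    rows1, rows23 = [], []
    for al in ds.loci:
        for sp in ds.species:
            s = species_locus_stats(al, sp)
            rows1.append({k: getattr(s, k) for k in (
                "locus_id", "species", "n", "retained_length", "S", "eta", "h",
                "hd", "pi", "k", "theta_w", "theta_w_site", "d_taj", "d_fl",
                "f_fl", "fs")})
        for a, b in ds.species_pairs():
            p = pair_locus_stats(al, a, b, n_perm=n_perm, frame=frame, rng=rng)
            row = {k: getattr(p, k) for k in (
                "locus_id", "species_a", "species_b", "s1", "s2", "sp", "fp",
                "e_sp", "ka", "ks", "ka_ks", "phi_st", "phi_p", "dxy")}
            row["sig"] = (
                "**" if p.phi_p <= 0.01 else "*" if p.phi_p <= 0.05 else ""
            ) if not math.isnan(p.phi_p) else ""
            rows23.append(row)
    t1 = pd.DataFrame(rows1)
    t23 = pd.DataFrame(rows23)
    num1 = t1.select_dtypes("number").drop(columns=["n"])
    mean1 = t1.groupby("species")[num1.columns].agg(["mean", "sem"])
    num23 = t23.select_dtypes("number")
    mean23 = t23.groupby(["species_a", "species_b"])[num23.columns].agg(["mean", "sem"])
    return {
        "diversity": t1,
        "diversity_means": mean1,
        "pairwise": t23,
        "pairwise_means": mean23,
    }


def write_summary_report(report: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t")
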