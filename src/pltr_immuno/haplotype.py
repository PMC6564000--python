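"""Two-locus haplotype frequency estimation and association testing.

HLA class II alleles arrive as unphased genotypes: each subject carries an
unordered allele pair at DRB1 and at DQB1, and only double-heterozygous
subjects are phase-ambiguous.  Haplotype frequencies are estimated by the
standard EM algorithm over phase ambiguity (gene counting), initialised at
linkage equilibrium (product of marginal allele frequencies) so the rare
symmetric two-fixed-point configuration resolves deterministically.

The association statistic for a target haplotype (e.g. DRB1*15-DQB1*06) is
the difference in EM-estimated haplotype frequency between outcome groups,
with a permutation p-value obtained by re-running both EMs under shuffled
outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable, CohortError


class HaplotypeError(ValueError):
    pass


@dataclass
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies."""

    freq: dict[tuple[str, str], float]
    loglik: float
    n_iter: int
    converged: bool

    def get(self, haplotype: tuple[str, str]) -> float:
        return self.freq.get(tuple(haplotype), 0.0)


def _phasings(pair):
    """Possible ordered haplotype assignments for one subject.

    Returns a list of ``((h1, h2), multiplicity)`` with multiplicity 2 when
    the two haplotypes differ (unordered genotype counts both orders).
    """
    (a1, a2), (b1, b2) = pair
    opts = [((a1, b1), (a2, b2))]
    if a1 != a2 and b1 != b2:
        opts.append(((a1, b2), (a2, b1)))
    out = []
    for h1, h2 in opts:
        m = 2 if h1 != h2 else 1
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        out.append((key, m))
    # the two phasings of a double heterozygote are always distinct
    return out


def em_haplotype_freqs(genotypes, tol: float = 1e-10,
                       max_iter: int = 1000) -> HaplotypeFreqs:
    """EM haplotype frequencies from phase-unknown two-locus genotypes.

    ``genotypes`` is a sequence of ``((a1, a2), (b1, b2))`` allele pairs.
    The log-likelihood is checked to be non-decreasing at every iteration;
    convergence is a log-likelihood change below ``tol``.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise HaplotypeError("need at least one genotyped subject")
    n = len(genotypes)

    # enumerate haplotypes appearing in any phasing
    subj_phasings = [_phasings(g) for g in genotypes]
    haps = sorted({h for ph in subj_phasings for (h1, h2), _ in ph for h in (h1, h2)})
    hidx = {h: i for i, h in enumerate(haps)}
    H = len(haps)

    # flat arrays: one row per (subject, phasing)
    sub, i1, i2, mult = [], [], [], []
    for s, ph in enumerate(subj_phasings):
        for (h1, h2), m in ph:
            sub.append(s); i1.append(hidx[h1]); i2.append(hidx[h2]); mult.append(m)
    sub = np.array(sub); i1 = np.array(i1); i2 = np.array(i2)
    mult = np.array(mult, dtype=float)

    # linkage-equilibrium start from marginal allele frequencies
    a_counts, b_counts = {}, {}
    for (a1, a2), (b1, b2) in genotypes:
        for a in (a1, a2):
            a_counts[a] = a_counts.get(a, 0) + 1
        for b in (b1, b2):
            b_counts[b] = b_counts.get(b, 0) + 1
    f = np.array([a_counts[h[0]] * b_counts[h[1]] for h in haps], dtype=float)
    f /= f.sum()

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = mult * f[i1] * f[i2]
        denom = np.bincount(sub, weights=p, minlength=n)
        if (denom <= 0).any():
            # a phasing lost all mass (can only happen at the start)
            f = np.where(f < 1e-12, 1e-12, f)
            f /= f.sum()
            continue
        new_loglik = float(np.log(denom).sum())
        if new_loglik < loglik - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        w = p / denom[sub]
        counts = (np.bincount(i1, weights=w, minlength=H)
                  + np.bincount(i2, weights=w, minlength=H))
        f = counts / (2.0 * n)
        if new_loglik - loglik < tol:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik
    if not converged:
        import warnings
        warnings.warn("haplotype EM hit max_iter without converging",
                      RuntimeWarning, stacklevel=2)
    return HaplotypeFreqs(
        freq={h: float(x) for h, x in zip(haps, f)},
        loglik=loglik, n_iter=it, converged=converged)


# ---------------------------------------------------------------------------
# association test
# ---------------------------------------------------------------------------

@dataclass
class HaploAssocResult:
    target: tuple[str, str]
    statistic: float          # freq(case) - freq(control)
    p_value: float
    freq_pooled: float
    freq_case: float
    freq_control: float
    n_used: int
    n_perm: int
    target_observed: bool = True


def extract_pairs(cohort: CohortTable, locus1: str, locus2: str):
    """Pull ``(locus_a1, locus_a2)`` columns into unphased pairs.

    Returns ``(pairs, case_mask)`` over subjects complete at both loci and
    the outcome.
    """
    cols = [f"{locus1}_a1", f"{locus1}_a2", f"{locus2}_a1", f"{locus2}_a2"]
    for c in cols:
        if c not in cohort.data.columns:
            raise CohortError(f"missing allele column {c!r}")
    out_spec = cohort.outcome_spec
    df = cohort.data
    cc = ~df[cols + [out_spec.name]].isna().any(axis=1)
    sub = df.loc[cc]
    pairs = [((r[cols[0]], r[cols[1]]), (r[cols[2]], r[cols[3]]))
             for _, r in sub.iterrows()]
    case = (sub[out_spec.name] != out_spec.reference_level).to_numpy()
    return pairs, case


def _canonical(haplotype):
    return tuple(haplotype)


def haplotype_assoc_test(cohort: CohortTable, locus1: str, locus2: str,
                         target: tuple[str, str], n_perm: int = 1000,
                         seed: int = 0) -> HaploAssocResult:
    """Permutation test for a target haplotype's frequency difference.

    The statistic is the EM frequency of ``target`` among cases minus among
    controls; its null distribution is obtained by permuting outcome labels
    and re-running both EM fits.
    """
    if n_perm < 100:
        raise HaplotypeError("n_perm must be at least 100")
    pairs, case = extract_pairs(cohort, locus1, locus2)
    n = len(pairs)
    if n == 0 or case.sum() == 0 or case.sum() == n:
        raise HaplotypeError("need genotyped subjects in both outcome groups")
    target = _canonical(target)

    pooled = em_haplotype_freqs(pairs)
    alleles1 = {a for (p1, _p2) in pairs for a in p1}
    alleles2 = {b for (_p1, p2) in pairs for b in p2}
    if target[0] not in alleles1 or target[1] not in alleles2:
        return HaploAssocResult(target, 0.0, 1.0, 0.0, 0.0, 0.0,
                                n, n_perm, target_observed=False)

    idx = np.arange(n)

    def stat(mask):
        f_case = em_haplotype_freqs([pairs[i] for i in idx[mask]]).get(target)
        f_ctrl = em_haplotype_freqs([pairs[i] for i in idx[~mask]]).get(target)
        return f_case - f_ctrl, f_case, f_ctrl

    obs, f_case, f_ctrl = stat(case)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(case)
        s, _, _ = stat(perm)
        if abs(s) >= abs(obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return HaploAssocResult(target, float(obs), float(p),
                            pooled.get(target), float(f_case), float(f_ctrl),
                            n, n_perm)


__all__ = [
    "HaplotypeFreqs", "HaploAssocResult", "HaplotypeError",
    "em_haplotype_freqs", "haplotype_assoc_test", "extract_pairs",
]
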