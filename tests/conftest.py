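"""Shared fixtures: small pedigrees, an independent brute-force IBD oracle,
and helpers for simulating the adjusted phenotype directly from the
variance-components model."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from pedscan.pedigree import Individual, Pedigree, compute_kinship


def _ped(rows, fam="F1"):
    sex_fix = {}
    for iid, fat, mot, sex in rows:
        sex_fix[iid] = sex
    return Pedigree(
        [Individual(iid, fam, fat, mot, sex) for iid, fat, mot, sex in rows]
    )


@pytest.fixture
def trio():
    return _ped(
        [
            ("dad", None, None, "male"),
            ("mom", None, None, "female"),
            ("kid", "dad", "mom", "male"),
        ]
    )


@pytest.fixture
def nuclear5():
    return _ped(
        [
            ("dad", None, None, "male"),
            ("mom", None, None, "female"),
            ("s1", "dad", "mom", "male"),
            ("s2", "dad", "mom", "female"),
            ("s3", "dad", "mom", "male"),
        ]
    )


@pytest.fixture
def halfsib5():
    return _ped(
        [
            ("dad", None, None, "male"),
            ("m1", None, None, "female"),
            ("m2", None, None, "female"),
            ("c1", "dad", "m1", "male"),
            ("c2", "dad", "m2", "female"),
        ]
    )


@pytest.fixture
def inbred5():
    """Full-sib mating: offspring x has inbreeding coefficient 1/4."""
    return _ped(
        [
            ("gp", None, None, "male"),
            ("gm", None, None, "female"),
            ("s1", "gp", "gm", "male"),
            ("s2", "gp", "gm", "female"),
            ("x", "s1", "s2", "male"),
        ]
    )


@pytest.fixture
def threegen8():
    """Three generations, 8 members, 3 founders."""
    return _ped(
        [
            ("gp1", None, None, "male"),
            ("gp2", None, None, "female"),
            ("sp", None, None, "female"),
            ("c1", "gp1", "gp2", "male"),
            ("c2", "gp1", "gp2", "female"),
            ("g1", "c1", "sp", "male"),
            ("g2", "c1", "sp", "female"),
            ("g3", "c1", "sp", "male"),
        ]
    )


@pytest.fixture
def cousins8():
    """First cousins g1, g2 through sibs c1, c2."""
    return _ped(
        [
            ("gp1", None, None, "male"),
            ("gp2", None, None, "female"),
            ("sp1", None, None, "female"),
            ("sp2", None, None, "male"),
            ("c1", "gp1", "gp2", "male"),
            ("c2", "gp1", "gp2", "female"),
            ("g1", "c1", "sp1", "male"),
            ("g2", "sp2", "c2", "female"),
        ]
    )


# --------------------------------------------------------------------------
# independent brute-force oracle: full enumeration in pure python
# --------------------------------------------------------------------------

def brute_force_ibd(ped: Pedigree, observed: dict[str, int], maf: float):
    """Conditional expected IBD sharing by exhaustive pure-python enumeration.

    Enumerates every founder-allele value assignment and every transmission
    pattern, propagating (founder, slot) labels down the pedigree with
    plain dicts; weights are Hardy-Weinberg founder priors times uniform
    transmissions, zeroed where genotypes disagree.  Deliberately written
    without any pedscan descent machinery.
    """
    members = list(ped.members)
    founders = [m.individual_id for m in members if m.is_founder]
    nonf = [m for m in members if not m.is_founder]
    ids = [m.individual_id for m in members]
    n = len(ids)
    num = np.zeros((n, n))
    den = 0.0
    f_slots = [(f, a) for f in founders for a in (0, 1)]
    for values in itertools.product((0, 1), repeat=len(f_slots)):
        vmap = dict(zip(f_slots, values))
        prior = 1.0
        for v in values:
            prior *= maf if v else (1.0 - maf)
        for bits in itertools.product((0, 1), repeat=2 * len(nonf)):
            labels: dict[str, tuple] = {}
            for f in founders:
                labels[f] = ((f, 0), (f, 1))
            for k, m in enumerate(nonf):
                bp, bm = bits[2 * k], bits[2 * k + 1]
                labels[m.individual_id] = (
                    labels[m.father_id][bp],
                    labels[m.mother_id][bm],
                )
            ok = True
            for iid, g in observed.items():
                la, lb = labels[iid]
                if vmap[la] + vmap[lb] != g:
                    ok = False
                    break
            if not ok:
                continue
            den += prior
            for i in range(n):
                for j in range(n):
                    s = sum(
                        1
                        for a in labels[ids[i]]
                        for b in labels[ids[j]]
                        if a == b
                    )
                    num[i, j] += prior * 0.5 * s
    if den == 0:
        raise ValueError("genotypes inconsistent")
    return ids, num / den


def gene_drop_kinship_mc(ped: Pedigree, n_rep: int, seed: int):
    """Monte-Carlo kinship: P(two random alleles IBD) by naive gene dropping.

    Independent of compute_kinship; returns (ids, mean matrix, se matrix)
    of the per-replicate kinship realization 0.25 * sum of allele matches.
    """
    rng = np.random.default_rng(seed)
    members = list(ped.members)
    n = len(members)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    for _ in range(n_rep):
        labels = {}
        counter = itertools.count()
        for m in members:
            if m.is_founder:
                labels[m.individual_id] = (next(counter), next(counter))
            else:
                f = labels[m.father_id]
                mo = labels[m.mother_id]
                labels[m.individual_id] = (
                    f[rng.integers(2)],
                    mo[rng.integers(2)],
                )
        lab = [labels[m.individual_id] for m in members]
        phi = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                phi[i, j] = 0.25 * sum(
                    1 for a in lab[i] for b in lab[j] if a == b
                )
        s1 += phi
        s2 += phi ** 2
    mean = s1 / n_rep
    var = np.maximum(s2 / n_rep - mean ** 2, 0.0)
    return [m.individual_id for m in members], mean, np.sqrt(var / n_rep)


def simulate_R(peds, kin, sigma2_a, sigma2_e, rng, mean=0.0, shift_of_fam=None):
    """Draw the adjusted phenotype directly from N(mean, 2*Phi*s2a + I*s2e)."""
    rows = {}
    for p in peds:
        n = len(p)
        mu = mean + (shift_of_fam or {}).get(p.family_id, 0.0)
        a = np.zeros(n)
        if sigma2_a > 0:
            L = np.linalg.cholesky(kin[p.family_id].matrix2 + 1e-10 * np.eye(n))
            a = L @ rng.standard_normal(n) * np.sqrt(sigma2_a)
        e = rng.standard_normal(n) * np.sqrt(sigma2_e)
        for i, iid in enumerate(p.ids):
            rows[iid] = mu + a[i] + e[i]
    return pd.Series(rows)
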