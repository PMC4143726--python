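"""Single-marker identity-by-descent (IBD) sharing for pedigree relative pairs.

The matrix ``Pi`` holds, for each relative pair, the expected proportion of
alleles shared IBD at one marker given the observed genotypes there:

    pi_ij = E[ (1/2) * sum_{a,b} 1{allele a of i IBD allele b of j} | G ]

with *a, b* ranging over the two alleles of each individual.  The diagonal is
``1 + f_i`` (self-sharing, inbreeding-adjusted).  Unconditionally (marker
untyped) ``E[Pi] = 2 * Phi``, twice the kinship matrix.

Two estimators are provided: an exact one that enumerates inheritance
vectors (one bit per meiosis) jointly with founder-allele states weighted by
Hardy-Weinberg priors and Mendelian transmission, and a Monte-Carlo
rejection sampler for pedigrees beyond the enumeration limit.  Both are
strictly two-point: one marker at a time, no linkage map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pedigree import KinshipMatrix, Pedigree

# Cap on (inheritance vectors) x (founder-allele states) handled by the
# exact path; beyond it compute_ibd_exact raises IbdSizeError.
DEFAULT_STATE_LIMIT = 2 ** 24


class IbdError(ValueError):
    pass


class MendelianInconsistencyError(IbdError):
    """Observed genotypes have zero likelihood under Mendelian transmission."""


class IbdSizeError(IbdError):
    """Pedigree exceeds the exact-enumeration limit; use the Monte-Carlo path."""


class IbdConvergenceError(IbdError):
    """Rejection sampler accepted no draws within the attempt budget."""


class AlleleFrequencyError(IbdError):
    pass


@dataclass
class MarkerGenotypes:
    """Biallelic marker: minor-allele dosage (0/1/2, ``None`` = missing) per id."""

    marker_id: str
    chromosome: str
    position_bp: int
    dosages: dict[str, int | None]
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise IbdError(f"marker {self.marker_id!r}: position must be >= 1")
        for iid, d in self.dosages.items():
            if d is not None and d not in (0, 1, 2):
                raise IbdError(
                    f"marker {self.marker_id!r}: invalid dosage {d!r} for {iid!r}"
                )

    def dosage(self, individual_id: str) -> int | None:
        return self.dosages.get(individual_id)

    def flip(self) -> None:
        """Swap allele labels in place (dosage d -> 2 - d)."""
        self.dosages = {
            i: (None if d is None else 2 - d) for i, d in self.dosages.items()
        }
        if self.maf is not None:
            self.maf = 1.0 - self.maf


@dataclass
class IbdMatrix:
    """Pairwise expected IBD sharing proportions at one marker."""

    ids: tuple[str, ...]
    values: np.ndarray
    marker_id: str = ""
    family_id: str = ""
    mc_se: np.ndarray | None = None
    n_samples: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._index = {i: k for k, i in enumerate(self.ids)}

    def pi(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "IbdMatrix":
        idx = [self._index[i] for i in ids]
        return IbdMatrix(
            tuple(ids), self.values[np.ix_(idx, idx)], self.marker_id, self.family_id
        )


def prior_ibd(kin: KinshipMatrix, marker_id: str = "") -> IbdMatrix:
    """Unconditional expected sharing: 2*Phi (diagonal 1 + f)."""
    return IbdMatrix(kin.ids, kin.matrix2, marker_id, kin.family_id)


def estimate_allele_freq(
    geno: MarkerGenotypes,
    peds: Iterable[Pedigree],
    method: str = "founders_only",
) -> float:
    """Estimate the minor allele frequency from pedigree genotypes.

    ``founders_only`` counts alleles in pedigree founders (the natural
    reference population); ``all_counted`` counts every genotyped member.
    If the computed frequency exceeds 0.5 the marker's allele labels are
    flipped in place and the complementary frequency returned.
    """
    if method not in ("founders_only", "all_counted"):
        raise ValueError(f"unknown method {method!r}")
    total = 0
    n = 0
    for ped in peds:
        members = ped.founders if method == "founders_only" else ped.members
        for m in members:
            d = geno.dosage(m.individual_id)
            if d is not None:
                total += d
                n += 1
    if n == 0:
        raise AlleleFrequencyError(
            f"marker {geno.marker_id!r}: no non-missing genotypes in the "
            f"{method} reference set"
        )
    freq = total / (2.0 * n)
    if freq > 0.5:
        geno.flip()
        freq = 1.0 - freq
    geno.maf = freq
    return freq


# --------------------------------------------------------------------------
# descent machinery shared by the exact engine, the sampler, and gene-dropping
# --------------------------------------------------------------------------

def _meiosis_layout(ped: Pedigree):
    """Founder allele slots and the meiosis bit layout of a pedigree.

    Founder *k* (topological order) owns slots ``2k`` and ``2k + 1``.  Each
    non-founder has two meioses (paternal then maternal); bit ``b`` of a
    meiosis selects which of the parent's two alleles is transmitted.
    """
    founder_ordinal: dict[int, int] = {}
    meioses: list[tuple[int, int, int]] = []  # (child idx, parent idx, allele 0/1)
    for i, m in enumerate(ped.members):
        if m.is_founder:
            founder_ordinal[i] = len(founder_ordinal)
        else:
            meioses.append((i, ped.index_of(m.father_id), 0))
            meioses.append((i, ped.index_of(m.mother_id), 1))
    return founder_ordinal, meioses


def _phase_fixed_bits(ped: Pedigree) -> list[int]:
    """One meiosis index per transmitting founder, fixable by phase symmetry.

    Swapping a founder's two (a-priori exchangeable) alleles while flipping
    every meiosis that draws from that founder leaves genotype probabilities
    and realized sharing invariant, so enumeration may pin the first such
    meiosis of each founder to 0 and cover a fundamental domain: a 2^F
    reduction of the inheritance-vector space.
    """
    founder_ordinal, meioses = _meiosis_layout(ped)
    fixed: dict[int, int] = {}
    for k, (_, parent, _) in enumerate(meioses):
        if parent in founder_ordinal and parent not in fixed:
            fixed[parent] = k
    return sorted(fixed.values())


def drop_slots(ped: Pedigree, bits: np.ndarray) -> np.ndarray:
    """Resolve meiosis bits into founder-allele slot labels.

    ``bits`` has shape (n_draws, n_meioses); returns an integer array of
    shape (n_draws, n_members, 2) giving the founder slot carried by each
    allele of each member under each draw.
    """
    founder_ordinal, meioses = _meiosis_layout(ped)
    n_draws = bits.shape[0]
    slots = np.empty((n_draws, len(ped), 2), dtype=np.int32)
    for i, ordinal in founder_ordinal.items():
        slots[:, i, 0] = 2 * ordinal
        slots[:, i, 1] = 2 * ordinal + 1
    for k, (child, parent, which) in enumerate(meioses):
        b = bits[:, k]
        slots[:, child, which] = slots[np.arange(n_draws), parent, b]
    return slots


def _sharing_from_slots(slots: np.ndarray) -> np.ndarray:
    """Realized IBD sharing matrices from slot labels.

    (n_draws, n, 2) slots -> (n_draws, n, n) with entries
    (1/2) * #{(a, b): slot_ia == slot_jb}; diagonal 1 + f.
    """
    eq = slots[:, :, None, :, None] == slots[:, None, :, None, :]
    return 0.5 * eq.sum(axis=(3, 4))


def _founder_states(n_slots: int, maf: float):
    """All 2^n_slots founder-allele assignments with Hardy-Weinberg priors."""
    s = np.arange(2 ** n_slots, dtype=np.int64)
    states = ((s[:, None] >> np.arange(n_slots)) & 1).astype(np.int8)
    k = states.sum(axis=1)
    prior = (maf ** k) * ((1.0 - maf) ** (n_slots - k))
    return states, prior


def _typed_members(ped: Pedigree, geno: MarkerGenotypes):
    idx, obs = [], []
    for i, m in enumerate(ped.members):
        d = geno.dosage(m.individual_id)
        if d is not None:
            idx.append(i)
            obs.append(d)
    return np.asarray(idx, dtype=int), np.asarray(obs, dtype=np.int8)


def compute_ibd_exact(
    ped: Pedigree,
    geno: MarkerGenotypes,
    maf: float,
    state_limit: int = DEFAULT_STATE_LIMIT,
    chunk: int = 4096,
) -> IbdMatrix:
    """Exact conditional expectation of IBD sharing at one marker.

    Sums over every inheritance vector and every founder-allele state,
    weighting by the Hardy-Weinberg founder prior and conditioning on the
    observed genotypes (missing genotypes are marginalized).  Exact for any
    pedigree, including inbred ones, within the enumeration limit.
    """
    if not 0.0 <= maf <= 1.0:
        raise IbdError(f"maf must be in [0, 1], got {maf}")
    founder_ordinal, meioses = _meiosis_layout(ped)
    n_slots = 2 * len(founder_ordinal)
    n_meioses = len(meioses)
    typed_idx, typed_obs = _typed_members(ped, geno)
    # founder-phase symmetry: pin one meiosis per transmitting founder
    fixed = _phase_fixed_bits(ped)
    free = [k for k in range(n_meioses) if k not in set(fixed)]
    n_v = 2 ** len(free)
    n_states = 2 ** n_slots if len(typed_idx) else 1
    if n_v * n_states > state_limit:
        raise IbdSizeError(
            f"family {ped.family_id!r}: {n_v} reduced inheritance vectors x "
            f"{n_states} founder states exceeds the exact limit {state_limit}; "
            "use compute_ibd_montecarlo"
        )

    if len(typed_idx):
        states, prior = _founder_states(n_slots, maf)
        states_t = states.T  # (n_slots, n_states)
    num = np.zeros((len(ped), len(ped)))
    den = 0.0
    bit_cols = np.arange(len(free))
    for start in range(0, n_v, chunk):
        vs = np.arange(start, min(start + chunk, n_v), dtype=np.int64)
        bits = np.zeros((len(vs), n_meioses), dtype=np.int8)
        bits[:, free] = ((vs[:, None] >> bit_cols) & 1).astype(np.int8)
        slots = drop_slots(ped, bits)
        if len(typed_idx):
            mask = np.ones((len(vs), n_states), dtype=bool)
            for i, g in zip(typed_idx, typed_obs):
                dos = states_t[slots[:, i, 0]] + states_t[slots[:, i, 1]]
                mask &= dos == g
            pg = mask @ prior  # P(G | v), marginal over founder alleles
        else:
            pg = np.ones(len(vs))
        pi = _sharing_from_slots(slots)
        num += np.einsum("c,cij->ij", pg, pi)
        den += pg.sum()
    if den <= 0.0:
        raise MendelianInconsistencyError(
            f"marker {geno.marker_id!r} is Mendelian-inconsistent in "
            f"family {ped.family_id!r}"
        )
    return IbdMatrix(ped.ids, num / den, geno.marker_id, ped.family_id)


def compute_ibd_montecarlo(
    ped: Pedigree,
    geno: MarkerGenotypes,
    maf: float,
    n_samples: int = 10_000,
    seed: int = 0,
    max_attempts: int | None = None,
    is_state_limit: int = 4096,
) -> IbdMatrix:
    """Monte-Carlo estimate of the same conditional expectation.

    Inheritance vectors are sampled uniformly.  When the founder-allele
    state space is small (``<= is_state_limit`` states) each sampled vector
    is weighted by its exact genotype likelihood ``P(G | v)`` with founder
    alleles marginalized analytically (importance sampling); otherwise
    founder alleles are drawn from the Hardy-Weinberg prior and draws
    inconsistent with the observed genotypes are rejected.  Both routes
    estimate the same conditional expectation; ``n_samples`` is the number
    of weighted draws (importance route) or the accepted-sample target
    (rejection route, attempt budget default ``1000 * n_samples``).
    :class:`IbdConvergenceError` signals zero usable draws.  The result
    carries elementwise standard errors in ``mc_se``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    founder_ordinal, meioses = _meiosis_layout(ped)
    n_slots = 2 * len(founder_ordinal)
    n_meioses = len(meioses)
    typed_idx, typed_obs = _typed_members(ped, geno)
    n = len(ped)

    if not len(typed_idx) or 2 ** n_slots <= is_state_limit:
        # importance route: weight each v by P(G | v)
        if len(typed_idx):
            states, prior = _founder_states(n_slots, maf)
            states_t = states.T
        sw = 0.0
        sw2 = 0.0
        swp = np.zeros((n, n))
        swp2 = np.zeros((n, n))
        done = 0
        while done < n_samples:
            b = min(n_samples - done, 16384)
            done += b
            bits = rng.integers(0, 2, size=(b, n_meioses), dtype=np.int8)
            slots = drop_slots(ped, bits)
            if len(typed_idx):
                mask = np.ones((b, len(prior)), dtype=bool)
                for i, g in zip(typed_idx, typed_obs):
                    dos = states_t[slots[:, i, 0]] + states_t[slots[:, i, 1]]
                    mask &= dos == g
                w = mask @ prior
            else:
                w = np.ones(b)
            pi = _sharing_from_slots(slots)
            sw += w.sum()
            sw2 += (w ** 2).sum()
            swp += np.einsum("c,cij->ij", w, pi)
            swp2 += np.einsum("c,cij->ij", w, pi ** 2)
        if sw <= 0.0:
            raise IbdConvergenceError(
                f"marker {geno.marker_id!r}, family {ped.family_id!r}: all "
                f"{n_samples} sampled inheritance vectors had zero genotype "
                "likelihood"
            )
        mean = swp / sw
        var = np.maximum(swp2 / sw - mean ** 2, 0.0)
        ess = sw ** 2 / sw2
        se = np.sqrt(var / ess)
        return IbdMatrix(
            ped.ids, mean, geno.marker_id, ped.family_id,
            mc_se=se, n_samples=n_samples,
        )

    # rejection route for very many founders
    budget = max_attempts if max_attempts is not None else 1000 * n_samples
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    n_acc = 0
    attempted = 0
    batch = int(min(max(n_samples, 4096), 65536))
    while n_acc < n_samples and attempted < budget:
        b = min(batch, budget - attempted)
        attempted += b
        bits = rng.integers(0, 2, size=(b, n_meioses), dtype=np.int8)
        slots = drop_slots(ped, bits)
        alleles = (rng.random((b, n_slots)) < maf).astype(np.int8)
        keep = np.ones(b, dtype=bool)
        for i, g in zip(typed_idx, typed_obs):
            dos = (
                np.take_along_axis(alleles, slots[:, i, 0][:, None], 1)[:, 0]
                + np.take_along_axis(alleles, slots[:, i, 1][:, None], 1)[:, 0]
            )
            keep &= dos == g
        slots = slots[keep]
        take = min(len(slots), n_samples - n_acc)
        if take == 0:
            continue
        pi = _sharing_from_slots(slots[:take])
        s1 += pi.sum(axis=0)
        s2 += (pi ** 2).sum(axis=0)
        n_acc += take
    if n_acc == 0:
        raise IbdConvergenceError(
            f"marker {geno.marker_id!r}, family {ped.family_id!r}: no consistent "
            f"configurations in {attempted} attempts"
        )
    mean = s1 / n_acc
    var = np.maximum(s2 / n_acc - mean ** 2, 0.0)
    se = np.sqrt(var / n_acc)
    return IbdMatrix(
        ped.ids, mean, geno.marker_id, ped.family_id, mc_se=se, n_samples=n_acc
    )


def write_ibd_triplets(ibds: Iterable[IbdMatrix], path: str | Path) -> None:
    """Write IBD matrices as a sparse triplet table (id_i, id_j, pi).

    One commented header per (marker, pedigree) block; zero entries and the
    lower triangle are omitted.
    """
    with Path(path).open("w") as fh:
        for ibd in ibds:
            fh.write(f"# marker={ibd.marker_id} family={ibd.family_id}\n")
            for a in range(len(ibd.ids)):
                for b in range(a, len(ibd.ids)):
                    v = ibd.values[a, b]
                    if v != 0.0:
                        fh.write(f"{ibd.ids[a]}\t{ibd.ids[b]}\t{v:.10g}\n")


def read_ibd_triplets(path: str | Path) -> list[IbdMatrix]:
    """Read a triplet table written by :func:`write_ibd_triplets`."""
    blocks: list[tuple[str, str, dict[tuple[str, str], float]]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = dict(kv.split("=", 1) for kv in line[1:].split())
                blocks.append((meta.get("marker", ""), meta.get("family", ""), {}))
            else:
                a, b, v = line.split("\t")
                blocks[-1][2][(a, b)] = float(v)
    out = []
    for marker, family, entries in blocks:
        ids = sorted({i for pair in entries for i in pair})
        index = {i: k for k, i in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        for (a, b), v in entries.items():
            vals[index[a], index[b]] = v
            vals[index[b], index[a]] = v
        out.append(IbdMatrix(tuple(ids), vals, marker, family))
    return out
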