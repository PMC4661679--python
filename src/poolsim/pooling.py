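"""Stratified cohort sampling and pool construction.

The viable population is stratified by sex x case status and each replicate
cohort is drawn by simple random sampling without replacement within strata.
Pools of fixed size ``g`` are then formed uniformly at random within each
stratum, so every pool is homogeneous in sex and case status (case pools
contain cases only).  Pool-level covariates are *sums* over members, exactly
as they enter the pooled logistic model.

Because sampling is outcome-dependent (cases are over-represented relative to
their population prevalence), each pool carries a fixed offset
``ln(case pools / control pools)`` for its sex, which corrects the logistic
intercept for the sampling design.

The reference allocation is 10 male-control, 18 female-control, 12 male-case
and 5 female-case pools (45 pools in total); an integer ``scale`` multiplies
all four counts while leaving the offsets unchanged, and ``g`` = 1 recovers an
individual-level analysis with the same design offsets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_generator
from .errors import InsufficientStratumError, ParameterError, PartitionError

#: stratum label -> (sex, case) codes
STRATA: dict[str, tuple[int, int]] = {
    "male_control": (1, 0),
    "female_control": (0, 0),
    "male_case": (1, 1),
    "female_case": (0, 1),
}


@dataclass
class PoolAllocation:
    """Number of pools per sex x case stratum, pool size, and scale."""

    pools_male_control: int = 10
    pools_female_control: int = 18
    pools_male_case: int = 12
    pools_female_case: int = 5
    g: int = 5
    scale: int = 1

    def validate(self) -> None:
        if self.g < 1:
            raise ParameterError(f"pool size g must be >= 1, got {self.g}")
        if self.scale < 1:
            raise ParameterError(f"scale must be >= 1, got {self.scale}")
        for name in STRATA:
            if getattr(self, f"pools_{name}") < 0:
                raise ParameterError(f"pool count for {name} must be >= 0")

    def pools_in(self, stratum: str) -> int:
        return getattr(self, f"pools_{stratum}") * self.scale

    def members_in(self, stratum: str) -> int:
        return self.pools_in(stratum) * self.g

    @property
    def total_pools(self) -> int:
        return sum(self.pools_in(s) for s in STRATA)

    @property
    def cohort_size(self) -> int:
        return self.total_pools * self.g


def compute_offset(alloc: PoolAllocation, sex: int) -> float:
    """Sampling-design offset ``ln(case pools / control pools)`` for a sex.

    The reference counts give ln(12/10) = 0.1823 for males and ln(5/18) =
    -1.2809 for females; the offset depends only on the count ratio, so it is
    invariant to ``scale``.
    """
    if sex == 1:
        cases, controls = alloc.pools_male_case, alloc.pools_male_control
    elif sex == 0:
        cases, controls = alloc.pools_female_case, alloc.pools_female_control
    else:
        raise ParameterError(f"sex must be 0 or 1, got {sex}")
    if controls <= 0:
        raise ParameterError(f"zero control pools for sex={sex}")
    return float(np.log(cases / controls))


def stratum_indices(pop: pd.DataFrame, viable_only: bool = True) -> dict[str, np.ndarray]:
    """Positional row indices of each sex x case stratum of a population."""
    z = pop["z"].to_numpy()
    case = pop["y_case"].to_numpy()
    mask = pop["viable"].to_numpy().astype(bool) if (viable_only and "viable" in pop) \
        else np.ones(len(pop), dtype=bool)
    out = {}
    for name, (sex, is_case) in STRATA.items():
        out[name] = np.flatnonzero(mask & (z == sex) & (case == is_case))
    return out


def sample_stratum_indices(
    strata: dict[str, np.ndarray], alloc: PoolAllocation, rng
) -> dict[str, np.ndarray]:
    """Simple random sample without replacement from each stratum.

    Returns, per stratum, the positional indices of the sampled members (in
    random order).  Raises :class:`InsufficientStratumError` naming the first
    stratum that cannot supply its required count.
    """
    alloc.validate()
    rng = as_generator(rng)
    out = {}
    for name in STRATA:
        need = alloc.members_in(name)
        avail = strata[name]
        if need > avail.size:
            raise InsufficientStratumError(name, avail.size, need)
        take = rng.choice(avail.size, size=need, replace=False)
        out[name] = avail[take]
    return out


def sample_cohort(viable_pop: pd.DataFrame, alloc: PoolAllocation, rng) -> pd.DataFrame:
    """Draw one replicate cohort from the viable population.

    The result keeps the population's index values and gains a ``stratum``
    column; its size is ``alloc.cohort_size`` (45 * scale * g).
    """
    strata = stratum_indices(viable_pop)
    sampled = sample_stratum_indices(strata, alloc, rng)
    parts = []
    for name, idx in sampled.items():
        part = viable_pop.iloc[idx].copy()
        part["stratum"] = name
        parts.append(part)
    return pd.concat(parts, axis=0)


def form_pools(cohort: pd.DataFrame, alloc: PoolAllocation, rng) -> pd.DataFrame:
    """Partition a cohort into pools of size ``g`` and compute pool sums.

    Within each stratum the members are permuted uniformly at random and cut
    into consecutive blocks of ``g``; every member lands in exactly one pool.
    Returns one row per pool with columns ``sex``, ``is_case_pool``,
    ``sum_w1``, ``sum_w2``, ``sum_z``, ``sum_wga``, ``offset`` and
    ``member_ids`` (tuple of cohort index labels).
    """
    alloc.validate()
    rng = as_generator(rng)
    if "stratum" in cohort:
        labels = cohort["stratum"].to_numpy()
    else:
        z = cohort["z"].to_numpy()
        case = cohort["y_case"].to_numpy()
        rev = {v: k for k, v in STRATA.items()}
        labels = np.array([rev[(int(s), int(c))] for s, c in zip(z, case)])
    rows = []
    for name, (sex, is_case) in STRATA.items():
        pos = np.flatnonzero(labels == name)
        n_pools = alloc.pools_in(name)
        if pos.size != n_pools * alloc.g:
            raise PartitionError(
                f"stratum {name!r} has {pos.size} members; "
                f"cannot form {n_pools} pools of {alloc.g}"
            )
        if n_pools == 0:
            continue
        perm = pos[rng.permutation(pos.size)].reshape(n_pools, alloc.g)
        offset = compute_offset(alloc, sex)
        for members in perm:
            sub = cohort.iloc[members]
            rows.append({
                "sex": sex,
                "is_case_pool": is_case,
                "sum_w1": float(sub["w1"].sum()),
                "sum_w2": float(sub["w2"].sum()),
                "sum_z": float(sub["z"].sum()),
                "sum_wga": float(sub["w_ga"].sum()),
                "offset": offset,
                "member_ids": tuple(cohort.index[members]),
            })
    return pd.DataFrame(rows)


def pooled_design(
    columns: dict[str, np.ndarray],
    sampled: dict[str, np.ndarray],
    alloc: PoolAllocation,
    rng,
    covariates: tuple[str, str, str, str] = ("w1", "w2", "z", "w_ga"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: pool-level design matrix straight from column arrays.

    ``columns`` maps column names to full-population arrays; ``sampled`` is
    the output of :func:`sample_stratum_indices`.  Returns ``(X, y, offset)``
    where ``X`` has the four covariate-sum columns in ``covariates`` order.
    Equivalent to :func:`form_pools` followed by design assembly, but without
    DataFrame overhead in the replicate loop.
    """
    rng = as_generator(rng)
    xs, ys, offs = [], [], []
    for name, (sex, is_case) in STRATA.items():
        idx = sampled[name]
        n_pools = alloc.pools_in(name)
        if n_pools == 0:
            continue
        perm = idx[rng.permutation(idx.size)].reshape(n_pools, alloc.g)
        block = np.column_stack(
            [columns[c][perm].sum(axis=1) for c in covariates]
        )
        xs.append(block)
        ys.append(np.full(n_pools, is_case, dtype=float))
        offs.append(np.full(n_pools, compute_offset(alloc, sex)))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(offs)
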