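"""Brute-force Poisson lineage simulator for validating the timing estimators.

This is deliberately a separate code path from both the closed-form
estimators in :mod:`macroevo.clock` and the genome-scale simulator in
:mod:`macroevo.simulate`: it builds each case's tiny copy-lineage tree
explicitly, drops mutations branch by branch with per-branch Poisson draws,
and counts multiplicity classes by descendant enumeration. Agreement between
estimates on oracle-generated counts and the planted duplication times is the
package's correctness gate for the Case 1-5 equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class _Branch:
    t0: float
    t1: float | None = None
    children: list["_Branch"] = field(default_factory=list)

    def split(self, t: float) -> tuple["_Branch", "_Branch"]:
        self.t1 = t
        self.children = [_Branch(t), _Branch(t)]
        return self.children[0], self.children[1]

    def leaves(self) -> int:
        if not self.children:
            return 1
        return sum(c.leaves() for c in self.children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def _case_tree(case: int, t1: float, t2: float | None = None) -> list[_Branch]:
    """Roots of the surviving-copy lineage forest for each genotype case."""
    if case == 1:  # (2,0): other allele lost; survivor duplicates at t1
        root = _Branch(0.0)
        root.split(t1)
        return [root]
    if case == 2:  # (2,1): one allele duplicates at t1, the other is kept
        a = _Branch(0.0)
        a.split(t1)
        return [a, _Branch(0.0)]
    if case == 3:  # (3,0): duplication at t1, one product duplicates at t2
        root = _Branch(0.0)
        c1, _ = root.split(t1)
        c1.split(t2)
        return [root]
    if case == 4:  # (4,0): duplication at t1, both products double at t2
        root = _Branch(0.0)
        c1, c2 = root.split(t1)
        c1.split(t2)
        c2.split(t2)
        return [root]
    if case == 5:  # (2,2): genome doubling at t1 doubles both alleles
        a, b = _Branch(0.0), _Branch(0.0)
        a.split(t1)
        b.split(t1)
        return [a, b]
    raise ValueError(f"unknown case {case}")


def simulate_case_counts(
    case: int,
    t1: float,
    t2: float | None,
    expected_mutations: float,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Multiplicity-class counts from one brute-force realization.

    ``expected_mutations`` is the expected total count over all surviving
    branches; the per-unit-time rate is scaled to match so each case is
    simulated at comparable depth.
    """
    roots = _case_tree(case, t1, t2)
    branches = [b for r in roots for b in r.walk()]
    total_time = sum((b.t1 if b.t1 is not None else 1.0) - b.t0 for b in branches)
    rate = expected_mutations / total_time
    counts: dict[int, int] = {}
    for b in branches:
        span = (b.t1 if b.t1 is not None else 1.0) - b.t0
        k = int(rng.poisson(rate * span))
        if k:
            mult = b.leaves()
            counts[mult] = counts.get(mult, 0) + k
    return counts


def planted_times(case: int, t: float) -> tuple[float, float | None]:
    """Map a single planted time to the (t1, t2) pair each case expects.

    Two-step cases (3 and 4) plant the first duplication halfway to the
    second, so both estimates are exercised away from the boundaries.
    """
    if case in (3, 4):
        return t / 2.0, t
    return t, None
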