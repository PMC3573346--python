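"""Comparison statistics: phase lag index (PLI), weighted PLI, phase bifurcation index (PBI).

PLI counts the asymmetry of phase-difference signs around the real axis and
is therefore insensitive to coupling at exactly 0 or pi — the signature of
instantaneous crosstalk. It is deliberately NOT rotation invariant: rotating
all angles by a constant changes which side of the real axis they fall on.
PBI contrasts the phase locking of two trial populations against their
pooled locking. Neither statistic carries an analytic null distribution, so
significance comes from label-permutation wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circstats import AngleSample, plv
from .exceptions import InvalidInputError, UndefinedStatisticError
from .ranktest import TestResult, permutation_pvalue

__all__ = [
    "ComplexSample",
    "pli",
    "wpli",
    "pbi",
    "pli_significance",
    "pbi_significance",
]


@dataclass(frozen=True)
class ComplexSample:
    """Per-trial cross-spectral terms X = A*exp(i*theta)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=complex))
        if v.ndim != 1 or v.size < 1:
            raise InvalidInputError("ComplexSample requires a non-empty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("ComplexSample values must all be finite")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


def pli(sample: AngleSample, signed: bool = False) -> float:
    """Phase Lag Index |<sign(sin theta)>| over trials.

    Angles exactly on the real axis (theta in {0, pi}) contribute sign 0 and
    dilute the index toward 0 rather than being dropped; the average is over
    all trials. ``signed=True`` returns the mean sign itself (in [-1, 1]),
    which distinguishes leading from lagging phases; the default magnitude
    does not.
    """
    mean_sign = float(np.mean(np.sign(np.sin(sample.angles))))
    return mean_sign if signed else abs(mean_sign)


def wpli(sample: ComplexSample) -> float:
    """Weighted PLI |<Im X>| / <|Im X|> from per-trial cross-spectral terms.

    Since sign(sin theta) = sign(Im X), the numerator |<|Im X|*sign(sin theta)>|
    reduces to |<Im X>|. Equals 1 when all imaginary parts share a sign and
    equals PLI when all |Im X| are equal.
    """
    imag = np.imag(sample.values)
    denom = float(np.mean(np.abs(imag)))
    if denom == 0.0:
        raise UndefinedStatisticError("WPLI undefined: all imaginary parts are exactly zero (0/0)")
    return float(abs(np.mean(imag)) / denom)


def pbi(pop1: AngleSample, pop2: AngleSample) -> float:
    """Phase Bifurcation Index (PLV1 - PLVall) * (PLV2 - PLVall).

    PLVall is computed on the pooled trials from both populations. The index
    is positive when both populations are locked but at different angles
    (the bimodal split the index was designed for), negative when one
    population is locked and the other is not, and near zero when the
    populations match.
    """
    z1 = np.sum(np.exp(1j * pop1.angles))
    z2 = np.sum(np.exp(1j * pop2.angles))
    plv1 = abs(z1) / pop1.n
    plv2 = abs(z2) / pop2.n
    # pooled PLV from the two partial resultants: commutative in the two
    # populations, so pbi(a, b) == pbi(b, a) bit-exactly
    plv_all = abs(z1 + z2) / (pop1.n + pop2.n)
    return float((plv1 - plv_all) * (plv2 - plv_all))


def _pli_contrast(a: AngleSample, b: AngleSample) -> float:
    return abs(pli(a) - pli(b))


def _abs_pbi(a: AngleSample, b: AngleSample) -> float:
    return abs(pbi(a, b))


def pli_significance(
    pop1: AngleSample,
    pop2: AngleSample,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> TestResult:
    """Permutation test on |PLI(pop1) - PLI(pop2)| (default 1000 permutations)."""
    p, _ = permutation_pvalue(_pli_contrast, pop1, pop2, n_permutations=n_permutations, seed=seed)
    return TestResult(
        method="PLI",
        statistic=_pli_contrast(pop1, pop2),
        p_value=p,
        n1=pop1.n,
        n2=pop2.n,
        mode="permutation",
        n_permutations=n_permutations,
        seed=seed,
        extra={"pli_1": pli(pop1), "pli_2": pli(pop2),
               "signed_mean_1": pli(pop1, signed=True), "signed_mean_2": pli(pop2, signed=True)},
    )


def pbi_significance(
    pop1: AngleSample,
    pop2: AngleSample,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> TestResult:
    """Permutation test on |PBI(pop1, pop2)| (default 1000 permutations)."""
    p, _ = permutation_pvalue(_abs_pbi, pop1, pop2, n_permutations=n_permutations, seed=seed)
    return TestResult(
        method="PBI",
        statistic=pbi(pop1, pop2),
        p_value=p,
        n1=pop1.n,
        n2=pop2.n,
        mode="permutation",
        n_permutations=n_permutations,
        seed=seed,
    )
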