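"""Two-state thermodynamics of hairpin self-priming.

The evolving "organism" here is Oli, a ~107-nt single-stranded DNA designed so
that its 3' terminus can pair with a complementary tract near its 5' end.  When
that stem forms, a polymerase can extend the 3' end along the molecule's own 5'
arm ("self-priming"), producing the extension that later recruits the second
PCR primer.  Whether the stem forms depends on temperature.

Full secondary-structure prediction is deliberately out of scope.  All the
selection model needs is "can the 3' end pair and prime, and how does that
propensity fall with temperature", so the phenotype is reduced to a single
perfect-complementarity stem scored by a two-state (folded/unfolded) model:

    dG(T) = (L - 1) * (dH_stack - T * dS_stack) + dG_loop

with L the stem length in base pairs, per-stack enthalpy/entropy shared by all
stacks, and a temperature-independent loop-closure penalty.  The folded
fraction is the Boltzmann two-state expression 1 / (1 + exp(dG / RT)).
Defaults are calibrated so the ancestral stem is stable (dG < 0) from 45 to
55 degC and unstable (dG > 0) at 65 degC and above, matching the designed
behaviour of the founding molecule; its midpoint sits at 60.0 degC.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "ThermoParams",
    "Stem",
    "reverse_complement",
    "find_self_priming_stem",
    "stem_free_energy",
    "p_self_prime",
    "extend_by_self_priming",
    "celsius_to_kelvin",
    "DEFAULT_MIN_STEM",
]

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

DEFAULT_MIN_STEM = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T."""


class NotExtendableError(ValueError):
    """No self-priming stem: the molecule cannot extend its 3' end."""


def _check_alphabet(seq: str) -> str:
    s = seq.upper()
    if not s or not _VALID.issuperset(s):
        bad = sorted(set(s) - _VALID) if s else ["<empty>"]
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (uppercase ACGT only)."""
    return _check_alphabet(seq).translate(_COMPLEMENT)[::-1]


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Two-state stem stability parameters.

    dh_per_stack : kcal/mol per base-pair stack (negative, stabilising).
    ds_per_stack : kcal/(mol K) per stack (negative).
    loop_penalty : kcal/mol, temperature-independent cost of closing the loop.
    """

    dh_per_stack: float = -8.0
    ds_per_stack: float = -0.0227
    loop_penalty: float = 3.5

    def __post_init__(self) -> None:
        if self.dh_per_stack >= 0 or self.ds_per_stack >= 0:
            raise ValueError("per-stack dH and dS must be negative")
        if self.loop_penalty <= 0:
            raise ValueError("loop penalty must be positive")


@dataclass(frozen=True)
class Stem:
    """A perfect duplex between the 3' terminus and an internal tract.

    Spans are 1-based inclusive (three_prime_span ends at the final base).
    """

    three_prime_span: tuple[int, int]
    partner_span: tuple[int, int]

    @property
    def length(self) -> int:
        return self.three_prime_span[1] - self.three_prime_span[0] + 1


@lru_cache(maxsize=200_000)
def find_self_priming_stem(seq: str, min_stem: int = DEFAULT_MIN_STEM) -> Stem | None:
    """Longest 3'-terminal suffix whose reverse complement occurs internally.

    The partner tract must end at least one base before the suffix starts (the
    two spans never overlap).  Ties between partner positions are broken in
    favour of the 5'-most occurrence.  Returns None when the longest perfect
    match is shorter than ``min_stem``.
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    s = _check_alphabet(seq)
    n = len(s)
    for length in range(n // 2, min_stem - 1, -1):
        suffix = s[n - length:]
        target = suffix.translate(_COMPLEMENT)[::-1]
        # partner must lie entirely within the first n - length bases
        pos = s.find(target, 0, n - length)
        if pos >= 0:
            return Stem(
                three_prime_span=(n - length + 1, n),
                partner_span=(pos + 1, pos + length),
            )
    return None


def stem_free_energy(stem: Stem, temp_k: float, params: ThermoParams | None = None) -> float:
    """dG(T) of a stem in kcal/mol; strictly increasing in temperature."""
    params = params or ThermoParams()
    L = stem.length
    if L < 2:
        raise ValueError("free energy undefined for stems shorter than 2 bp")
    stacks = L - 1
    return stacks * (params.dh_per_stack - temp_k * params.ds_per_stack) + params.loop_penalty


def p_self_prime(
    seq: str,
    temp_k: float,
    params: ThermoParams | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> float:
    """Two-state folded fraction of the best self-priming stem.

    Zero when no stem of at least ``min_stem`` bp exists; otherwise
    1 / (1 + exp(dG / RT)), which is non-increasing in temperature.
    """
    if temp_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    stem = find_self_priming_stem(seq, min_stem)
    if stem is None:
        return 0.0
    dg = stem_free_energy(stem, temp_k, params)
    import math

    x = dg / (GAS_CONSTANT * temp_k)
    if x > 500:
        return 0.0
    if x < -500:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


def extend_by_self_priming(seq: str, min_stem: int = DEFAULT_MIN_STEM) -> str:
    """Extension product of a folded molecule.

    The polymerase copies the template 5' of the partner tract, appending the
    reverse complement of that prefix to the 3' end.  For the founding
    molecule this appends the reverse complement of its first eight bases, so
    the product's new 3' terminus mirrors its 5' terminus exactly.  A partner
    tract starting at position 1 leaves nothing to copy (extension of length
    zero).
    """
    stem = find_self_priming_stem(seq, min_stem)
    if stem is None:
        raise NotExtendableError("no self-priming stem of sufficient length")
    prefix = seq[: stem.partner_span[0] - 1]
    if not prefix:
        return _check_alphabet(seq)
    return _check_alphabet(seq) + reverse_complement(prefix)
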