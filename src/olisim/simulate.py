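"""Desk-scale simulator of fold-or-hold selection on Oli populations.

One transfer of the protocol is: (1) molecules are challenged to fold and
self-prime at the transfer's temperature; (2) a primer-limited PCR in which
lineages that self-primed (and so can recruit both primers) grow
exponentially while unextended founders grow linearly, every new strand
mutating with the polymerase's error rate and consuming one primer from the
finite pool; (3) restriction digestion cleaves the self-primed extension;
(4) a bottleneck carries ~1e5 molecules to the next transfer.  Eleven
transfers are run per replicate under one of four temperature regimes, and
FASTA read sets are emitted at the sampled transfers (1, 3, 7, 11).

Copy counts are exact integers throughout (bottlenecks and extinctions are
sampled without continuum approximation) and every stage is deterministic
under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hairpin import (
    DEFAULT_MIN_STEM,
    ThermoParams,
    celsius_to_kelvin,
    extend_by_self_priming,
    find_self_priming_stem,
    p_self_prime,
    reverse_complement,
)
from .io import ancestor_sequence, primer_sequences, write_fasta
from .readprep import DEFAULT_ENZYMES, RestrictionEnzyme, digest_trim
from .stats import GrowthCurve

__all__ = [
    "TemperatureRegime",
    "MutationModel",
    "SimConfig",
    "OliPopulation",
    "SimResult",
    "make_regime",
    "mutate_seq",
    "self_priming_step",
    "pcr_amplify",
    "digest_population",
    "bottleneck_sample",
    "sequence_population",
    "standard_curve",
    "run_experiment",
    "REGIME_NAMES",
]

REGIME_NAMES = ("control", "sudden", "intermediate", "slow")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class TemperatureRegime:
    """Per-transfer self-priming temperature schedule (degC) for one treatment."""

    name: str
    temps: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.temps) < 1:
            raise ValueError("empty schedule")


def make_regime(name: str, n_transfers: int = 11) -> TemperatureRegime:
    """The four selection regimes: all start at 55 degC.

    control: constant 55.  The three change regimes rise to 70 by the final
    transfer with the same total increase (15 degC), differing only in rate:
    sudden = one +15 step (at transfer 2), intermediate = five +3 steps,
    slow = ten +1.5 steps (one per transfer).
    """
    if name == "control":
        temps = [55.0] * n_transfers
    elif name == "sudden":
        temps = [55.0] + [70.0] * (n_transfers - 1)
    elif name == "intermediate":
        temps, current = [55.0], 55.0
        for t in range(2, n_transfers + 1):
            if t % 2 == 1:  # steps at transfers 3, 5, 7, 9, 11
                current += 3.0
            temps.append(current)
    elif name == "slow":
        temps = [55.0 + 1.5 * (t - 1) for t in range(1, n_transfers + 1)]
    else:
        raise ValueError(f"unknown regime: {name!r}")
    return TemperatureRegime(name=name, temps=tuple(temps))


@dataclass(frozen=True)
class MutationModel:
    """Per-duplication mutation process of the error-prone polymerase.

    Defaults put the combined rate mid-range of 1-16 errors per kb of newly
    synthesized DNA: 8 substitutions and 0.8 indels per kb.  The substitution
    spectrum is uniform by default (rows = from-base ACGT, columns = to-base,
    zero diagonal) and user-configurable.
    """

    sub_rate: float = 0.008
    indel_rate: float = 0.0008
    spectrum: tuple = (
        (0.0, 1 / 3, 1 / 3, 1 / 3),
        (1 / 3, 0.0, 1 / 3, 1 / 3),
        (1 / 3, 1 / 3, 0.0, 1 / 3),
        (1 / 3, 1 / 3, 1 / 3, 0.0),
    )
    max_indel_len: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        mat = np.asarray(self.spectrum, dtype=float)
        if mat.shape != (4, 4) or np.any(np.diag(mat) != 0):
            raise ValueError("spectrum must be 4x4 with zero diagonal")
        if not np.allclose(mat.sum(axis=1), 1.0):
            raise ValueError("spectrum rows must sum to 1")

    @property
    def per_base_rate(self) -> float:
        return self.sub_rate + self.indel_rate


def mutate_seq(seq: str, model: MutationModel, rng: np.random.Generator) -> str:
    """One round of error-prone copying of a single new strand."""
    n_sub = rng.binomial(len(seq), model.sub_rate)
    n_indel = rng.binomial(len(seq), model.indel_rate)
    return _apply_mutations(seq, model, rng, n_sub, n_indel)


def _mutate_at_least_once(seq: str, model: MutationModel, rng: np.random.Generator) -> str:
    """Mutant copy conditioned on carrying at least one mutation event."""
    while True:
        n_sub = rng.binomial(len(seq), model.sub_rate)
        n_indel = rng.binomial(len(seq), model.indel_rate)
        if n_sub + n_indel:
            return _apply_mutations(seq, model, rng, n_sub, n_indel)


def _mutant_copies(
    seq: str, n: int, model: MutationModel, rng: np.random.Generator
) -> list[str]:
    """n mutant copies of seq, each with at least one mutation (batched draws)."""
    if n <= 4:
        return [_mutate_at_least_once(seq, model, rng) for _ in range(n)]
    length = len(seq)
    out: list[str] = []
    need = n
    while need:
        ns = rng.binomial(length, model.sub_rate, size=need)
        ni = rng.binomial(length, model.indel_rate, size=need)
        hit = (ns + ni) > 0
        for a, b in zip(ns[hit], ni[hit]):
            out.append(_apply_mutations(seq, model, rng, int(a), int(b)))
        need -= int(hit.sum())
    return out


from functools import lru_cache


@lru_cache(maxsize=32)
def _cum_spectrum(spectrum: tuple) -> np.ndarray:
    return np.cumsum(np.asarray(spectrum, dtype=float), axis=1)


def _distinct_positions(n: int, length: int, rng: np.random.Generator) -> list[int]:
    n = min(n, length)
    if n == 1:
        return [int(rng.integers(0, length))]
    if n * 4 >= length:
        return [int(p) for p in rng.permutation(length)[:n]]
    seen: set[int] = set()
    while len(seen) < n:  # rare collision re-draw
        seen.add(int(rng.integers(0, length)))
    return list(seen)


def _apply_mutations(
    seq: str, model: MutationModel, rng: np.random.Generator, n_sub: int, n_indel: int
) -> str:
    if n_sub + n_indel == 0:
        return seq
    cum = _cum_spectrum(model.spectrum)
    chars = list(seq)
    if n_sub:
        positions = _distinct_positions(n_sub, len(chars), rng)
        for pos in positions:
            row = cum[_BASE_INDEX[chars[pos]]]
            r = rng.random() * row[-1]
            chars[pos] = _BASES[0 if r < row[0] else 1 if r < row[1] else 2 if r < row[2] else 3]
    for _ in range(n_indel):
        pos = int(rng.integers(0, len(chars)))
        length = int(rng.integers(1, model.max_indel_len + 1))
        if rng.random() < 0.5:
            insert = [_BASES[i] for i in rng.integers(0, 4, size=length)]
            chars[pos:pos] = insert
        elif len(chars) > length:
            del chars[pos: pos + length]
    return "".join(chars) if chars else seq


@dataclass
class OliPopulation:
    """Multiset of molecule records: (sequence, extended flag) -> copy count."""

    counts: dict[tuple[str, bool], int] = field(default_factory=dict)
    transfer_index: int = 0

    @classmethod
    def founding(cls, copies: int, sequence: str | None = None) -> "OliPopulation":
        seq = sequence or ancestor_sequence()
        return cls(counts={(seq, False): int(copies)}, transfer_index=0)

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def extended_copies(self) -> int:
        return sum(c for (_, ext), c in self.counts.items() if ext)

    @property
    def extended_fraction(self) -> float:
        tot = self.total_copies
        return self.extended_copies / tot if tot else 0.0

    def genotype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (seq, _), c in self.counts.items():
            out[seq] = out.get(seq, 0) + c
        return out

    def add(self, seq: str, extended: bool, copies: int) -> None:
        if copies:
            key = (seq, extended)
            self.counts[key] = self.counts.get(key, 0) + int(copies)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one fold-or-hold experiment.

    Defaults are the protocol's stated conditions: populations founded from
    ~30 000 copies of the printed ancestor, 5e6 copies of each primer per
    reaction, 40 qPCR cycles, ~1e5-molecule bottlenecks, 11 transfers sampled
    at 1, 3, 7 and 11, and 56 replicates per regime.
    """

    regime: TemperatureRegime
    n_transfers: int = 11
    n_replicates: int = 56
    founding_copies: int = 30_000
    primer_copies: int = 5_000_000
    qpcr_cycles: int = 40
    bottleneck_size: int = 100_000
    mutation: MutationModel = field(default_factory=MutationModel)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    min_stem: int = DEFAULT_MIN_STEM
    max_primer_mm: int = 0
    seed: int = 0
    read_depth: int = 1000
    read_error_rate: float = 0.0
    sampled_transfers: tuple[int, ...] = (1, 3, 7, 11)

    def __post_init__(self) -> None:
        if min(
            self.n_transfers,
            self.n_replicates,
            self.founding_copies,
            self.primer_copies,
            self.qpcr_cycles,
            self.bottleneck_size,
            self.read_depth,
        ) < 1:
            raise ValueError("all counts must be positive")
        if len(self.regime.temps) < self.n_transfers:
            raise ValueError("regime schedule shorter than n_transfers")
        if self.bottleneck_size > self.founding_copies + 2 * self.primer_copies:
            raise ValueError("bottleneck exceeds primer-limited capacity")


def self_priming_step(
    pop: OliPopulation,
    temp_c: float,
    thermo: ThermoParams | None = None,
    rng: np.random.Generator | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> OliPopulation:
    """Challenge every copy to fold and extend at the given temperature.

    Each unextended copy independently self-primes with the two-state folded
    fraction of its best stem; successes are replaced by their extension
    product.  Copies already extended (digestion escapees) stay extended.
    """
    if pop.total_copies == 0:
        raise ValueError("empty population")
    thermo = thermo or ThermoParams()
    rng = rng if rng is not None else np.random.default_rng()
    temp_k = celsius_to_kelvin(temp_c)
    out = OliPopulation(transfer_index=pop.transfer_index)
    for (seq, extended), count in pop.counts.items():
        if extended:
            out.add(seq, True, count)
            continue
        p = p_self_prime(seq, temp_k, thermo, min_stem)
        n_fold = int(rng.binomial(count, p)) if 0 < p < 1 else count * int(p == 1.0)
        if n_fold:
            out.add(extend_by_self_priming(seq, min_stem), True, n_fold)
        out.add(seq, False, count - n_fold)
    return out


from functools import lru_cache as _lru_cache


@_lru_cache(maxsize=1)
def _footprints() -> tuple[str, str]:
    fwd, _rev = primer_sequences()
    return ancestor_sequence()[:25], reverse_complement(fwd)


def _primer_viable(seq: str, max_mm: int) -> bool:
    """Does an extended molecule still carry both primer footprints?

    The 3' footprint is the reverse complement of the forward primer (the
    self-primed extension); the 5' footprint is the ancestral 5' end the
    reverse primer was designed against.  Molecules failing either footprint
    by more than ``max_mm`` mismatches can bind only one primer and drop to
    linear growth.
    """
    anc5, tail = _footprints()
    if len(seq) < len(anc5) + len(tail):
        return False
    head, end = seq[: len(anc5)], seq[-len(tail):]
    if head == anc5 and end == tail:
        return True
    if max_mm == 0:
        return False
    head_mm = sum(a != b for a, b in zip(head, anc5))
    tail_mm = sum(a != b for a, b in zip(end, tail))
    return head_mm <= max_mm and tail_mm <= max_mm


def pcr_amplify(
    pop: OliPopulation,
    cycles: int,
    primer_copies: int,
    model: MutationModel | None = None,
    rng: np.random.Generator | None = None,
    max_primer_mm: int = 0,
) -> tuple[OliPopulation, GrowthCurve]:
    """Primer-limited PCR: exponential for extended lineages, linear otherwise.

    Per cycle every extended-lineage copy duplicates and every unextended
    founder gains one linear copy; each new strand passes through the
    mutation model and consumes one primer from the shared pool (both primers
    combined), so growth plateaus when primers exhaust.  Extended-lineage
    mutants that lose a primer footprint drop to the linear class.  Returns
    the amplified population and the per-cycle growth curve.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    model = model or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()
    pool = 2 * primer_copies

    exp_class: dict[str, int] = {}
    founders: dict[str, int] = {}
    linear_extra: dict[str, int] = {}
    for (seq, extended), count in pop.counts.items():
        target = exp_class if extended else founders
        target[seq] = target.get(seq, 0) + count

    founders_total = sum(founders.values())
    exp_total = sum(exp_class.values())
    linear_total = 0
    totals = [exp_total + founders_total]

    def p_any(seq: str) -> float:
        return 1.0 - (1.0 - model.per_base_rate) ** len(seq)

    for _cycle in range(cycles):
        exp_seqs = list(exp_class)
        demand = np.array(
            [exp_class[s] for s in exp_seqs] + [founders_total], dtype=np.int64
        )
        total_demand = int(demand.sum())
        if total_demand == 0 or pool == 0:
            totals.extend([totals[-1]] * (cycles - _cycle))
            break
        if total_demand <= pool:
            granted = demand
        else:
            granted = rng.multivariate_hypergeometric(demand, pool, method="marginals")
        pool -= int(granted.sum())

        # exponential duplications
        for seq, n_new in zip(exp_seqs, granted[:-1]):
            n_new = int(n_new)
            if not n_new:
                continue
            pm = p_any(seq)
            n_mut = int(rng.binomial(n_new, pm)) if pm > 0 else 0
            exp_class[seq] += n_new - n_mut
            exp_total += n_new - n_mut
            for mutant in _mutant_copies(seq, n_mut, model, rng):
                if _primer_viable(mutant, max_primer_mm):
                    exp_class[mutant] = exp_class.get(mutant, 0) + 1
                    exp_total += 1
                else:
                    linear_extra[mutant] = linear_extra.get(mutant, 0) + 1
                    linear_total += 1

        # linear copies of unextended founders
        n_lin = int(granted[-1])
        if n_lin:
            f_seqs = list(founders)
            f_counts = np.array([founders[s] for s in f_seqs], dtype=np.int64)
            if n_lin >= f_counts.sum():
                alloc = f_counts
            else:
                alloc = rng.multivariate_hypergeometric(f_counts, n_lin, method="marginals")
            for seq, n_new in zip(f_seqs, alloc):
                n_new = int(n_new)
                if not n_new:
                    continue
                pm = p_any(seq)
                n_mut = int(rng.binomial(n_new, pm)) if pm > 0 else 0
                if n_new - n_mut:
                    linear_extra[seq] = linear_extra.get(seq, 0) + n_new - n_mut
                for mutant in _mutant_copies(seq, n_mut, model, rng):
                    linear_extra[mutant] = linear_extra.get(mutant, 0) + 1
                linear_total += n_new

        totals.append(exp_total + founders_total + linear_total)

    out = OliPopulation(transfer_index=pop.transfer_index)
    for seq, count in exp_class.items():
        out.add(seq, True, count)
    for seqs in (founders, linear_extra):
        for seq, count in seqs.items():
            out.add(seq, False, count)
    curve = GrowthCurve(totals=np.asarray(totals[: cycles + 1], dtype=float))
    return out, curve


def digest_population(
    pop: OliPopulation, enzymes: Iterable[RestrictionEnzyme] = DEFAULT_ENZYMES
) -> OliPopulation:
    """Cleave the extended 3' ends; copy totals are conserved.

    Molecules whose cut sites mutated away survive uncut and remain extended
    (the digestion-escape route); everything else reverts to its trimmed,
    unextended form.
    """
    enzymes = tuple(enzymes)
    out = OliPopulation(transfer_index=pop.transfer_index)
    for (seq, extended), count in pop.counts.items():
        trimmed = digest_trim(seq, enzymes, mode="three_prime")
        out.add(trimmed, extended and trimmed == seq, count)
    return out


def bottleneck_sample(
    pop: OliPopulation, size: int, rng: np.random.Generator | None = None
) -> OliPopulation:
    """Sample ``size`` copies without replacement (identity if size >= total)."""
    if size < 1:
        raise ValueError("bottleneck size must be >= 1")
    total = pop.total_copies
    if total == 0:
        raise ValueError("empty population")
    if size >= total:
        return OliPopulation(counts=dict(pop.counts), transfer_index=pop.transfer_index)
    rng = rng if rng is not None else np.random.default_rng()
    keys = list(pop.counts)
    counts = np.array([pop.counts[k] for k in keys], dtype=np.int64)
    sampled = rng.multivariate_hypergeometric(counts, size, method="marginals")
    out = OliPopulation(transfer_index=pop.transfer_index)
    for (seq, extended), c in zip(keys, sampled):
        out.add(seq, extended, int(c))
    return out


def sequence_population(
    pop: OliPopulation,
    depth: int,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    treatment: str = "na",
    transfer: int = 0,
    replicate: int = 0,
) -> list[SeqRecord]:
    """Emit FASTA reads sampled proportionally to copy counts.

    Sampling is with replacement (depth may exceed the population), with an
    optional uniform per-base substitution error.  Read ids carry the
    (treatment, transfer, replicate) metadata.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    genotypes = pop.genotype_counts()
    seqs = sorted(genotypes)
    weights = np.array([genotypes[s] for s in seqs], dtype=float)
    weights /= weights.sum()
    draws = rng.multinomial(depth, weights)
    reads = []
    i = 0
    for seq, n in zip(seqs, draws):
        for _ in range(int(n)):
            obs = seq
            if error_rate > 0:
                n_err = rng.binomial(len(seq), error_rate)
                if n_err:
                    chars = list(seq)
                    for pos in rng.choice(len(chars), size=n_err, replace=False):
                        chars[pos] = _BASES[
                            (_BASE_INDEX[chars[pos]] + int(rng.integers(1, 4))) % 4
                        ]
                    obs = "".join(chars)
            reads.append(
                SeqRecord(
                    Seq(obs),
                    id=f"{treatment}|t{transfer}|r{replicate}|read{i}",
                    description="",
                )
            )
            i += 1
    return reads


def standard_curve(
    n0: int, cycles: int, primer_copies: int
) -> GrowthCurve:
    """Growth curve of a pre-extended standard: pure doubling to the primer cap.

    Standards need no self-priming, so every copy duplicates each cycle until
    the primer pool exhausts; no mutation is applied (the standards quantify
    growth, not evolution).
    """
    pool = 2 * primer_copies
    totals = [float(n0)]
    current = n0
    for _ in range(cycles):
        new = min(current, pool)
        current += new
        pool -= new
        totals.append(float(current))
    return GrowthCurve(totals=np.asarray(totals))


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    config: SimConfig
    curves: dict[tuple[int, int], GrowthCurve] = field(default_factory=dict)
    reads: dict[tuple[int, int], list[SeqRecord]] = field(default_factory=dict)
    extended_fractions: dict[tuple[int, int], float] = field(default_factory=dict)
    final_populations: dict[int, OliPopulation] = field(default_factory=dict)

    def growth_frame(self):
        import pandas as pd

        rows = []
        for (rep, transfer), curve in sorted(self.curves.items()):
            for cycle, total in enumerate(curve.totals):
                rows.append((rep, transfer, cycle, total))
        return pd.DataFrame(
            rows, columns=["replicate", "transfer", "cycle", "total_copies"]
        )


def run_experiment(cfg: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Run all replicates of one regime through 11 transfers.

    Per transfer: self-priming -> primer-limited mutagenic PCR -> restriction
    digestion -> bottleneck; reads are emitted at the sampled transfers.
    Fully reproducible: identical configs (including seed) give bit-identical
    outputs.
    """
    result = SimResult(config=cfg)
    root_ss = np.random.SeedSequence(cfg.seed)
    for rep, child in enumerate(root_ss.spawn(cfg.n_replicates), start=1):
        rng = np.random.default_rng(child)
        pop = OliPopulation.founding(cfg.founding_copies)
        for transfer in range(1, cfg.n_transfers + 1):
            temp = cfg.regime.temps[transfer - 1]
            pop = self_priming_step(pop, temp, cfg.thermo, rng, cfg.min_stem)
            result.extended_fractions[(rep, transfer)] = pop.extended_fraction
            pop, curve = pcr_amplify(
                pop, cfg.qpcr_cycles, cfg.primer_copies, cfg.mutation, rng,
                cfg.max_primer_mm,
            )
            result.curves[(rep, transfer)] = curve
            pop = digest_population(pop)
            pop = bottleneck_sample(pop, cfg.bottleneck_size, rng)
            pop.transfer_index = transfer
            if transfer in cfg.sampled_transfers:
                result.reads[(rep, transfer)] = sequence_population(
                    pop,
                    cfg.read_depth,
                    cfg.read_error_rate,
                    rng,
                    treatment=cfg.regime.name,
                    transfer=transfer,
                    replicate=rep,
                )
        result.final_populations[rep] = pop
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for (rep, transfer), reads in result.reads.items():
        write_fasta(reads, out_dir / f"{cfg.regime.name}_r{rep:02d}_t{transfer:02d}.fasta")
    result.growth_frame().to_csv(out_dir / "growth_curves.csv", index=False)
    manifest = {
        "regime": cfg.regime.name,
        "temps": list(cfg.regime.temps),
        "n_transfers": cfg.n_transfers,
        "n_replicates": cfg.n_replicates,
        "founding_copies": cfg.founding_copies,
        "primer_copies": cfg.primer_copies,
        "qpcr_cycles": cfg.qpcr_cycles,
        "bottleneck_size": cfg.bottleneck_size,
        "mutation": {
            "sub_rate": cfg.mutation.sub_rate,
            "indel_rate": cfg.mutation.indel_rate,
            "max_indel_len": cfg.mutation.max_indel_len,
        },
        "thermo": {
            "dh_per_stack": cfg.thermo.dh_per_stack,
            "ds_per_stack": cfg.thermo.ds_per_stack,
            "loop_penalty": cfg.thermo.loop_penalty,
        },
        "min_stem": cfg.min_stem,
        "max_primer_mm": cfg.max_primer_mm,
        "seed": cfg.seed,
        "read_depth": cfg.read_depth,
        "read_error_rate": cfg.read_error_rate,
        "sampled_transfers": list(cfg.sampled_transfers),
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def scaled_config(
    regime_name: str,
    n_replicates: int = 6,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A reduced-size configuration for desk-scale runs.

    Population sizes are scaled down together, preserving the full protocol's
    ~100x bottleneck-to-capacity ratio (founding 600, primer pool 2.5e4 per
    primer, bottleneck 500, 30 cycles) so that the exponential/linear growth
    contrast, the primer-limited plateau, the log-linear slope assay and the
    bottleneck all operate as at full size while a multi-regime experiment
    runs in minutes.
    """
    base = dict(
        regime=make_regime(regime_name),
        n_replicates=n_replicates,
        founding_copies=600,
        primer_copies=25_000,
        qpcr_cycles=30,
        bottleneck_size=500,
        read_depth=500,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
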