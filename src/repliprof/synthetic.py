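"""Ground-truth replication programs and synthetic sort-seq count data.

The simulator encodes a minimal origin-firing / fork-progression model:
each origin ``i`` sits at position ``x_i`` with a characteristic firing
time ``T_i`` (minutes) and, for the stochastic mode, a per-cell firing
probability ``q_i``.  Forks move at a constant velocity ``v`` (bp/min)
in both directions and terminate at chromosome ends.  The time at which
a locus ``x`` is replicated is the earliest arrival over origins,

    t(x) = min_i ( T_i + |x - x_i| / v ),

restricted to origins on the same chromosome.  An origin whose locus is
reached by a foreign fork strictly before its own firing time is
*passively replicated* (dormant); ties count as active.

Population DNA abundance assumes uniform residence across S phase:
a locus replicated at time ``t`` is present in two copies in the
fraction ``1 - t/T_S`` of sorted S-phase cells, giving

    A(x) = 2 - t(x) / T_S        (dimensionless, in [1, 2]).

Read counts are drawn per restriction fragment with expectation
proportional to ``A(midpoint) * length_bias(length)``, scaled to a
target sequencing depth.

Randomness: every public entry point takes a single integer seed which
is expanded through :class:`numpy.random.SeedSequence`; independent
columns/cells consume spawned child streams in a documented, stable
order (S-phase columns first, then controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .processing import CountMatrix, FragmentTable

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSpec",
    "Origin",
    "OriginProgram",
    "ReplicationTimeline",
    "AbundanceTrack",
    "simulate_timeline",
    "population_abundance",
    "synth_counts",
    "simulate_count_matrix",
    "random_genome",
    "random_origin_program",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with optional sequence.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.  Names must be unique and
        lengths strictly positive.
    sequences:
        Optional mapping name -> A/C/G/T(/N) string whose length must
        equal the declared chromosome length.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sequences: Mapping[str, str] | None = None

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        if self.sequences is not None:
            for name, length in self.chromosomes:
                if name not in self.sequences:
                    raise ConfigError(f"sequence missing for chromosome {name!r}")
                if len(self.sequences[name]) != length:
                    raise ConfigError(
                        f"sequence length {len(self.sequences[name])} != declared "
                        f"length {length} for chromosome {name!r}"
                    )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class Origin:
    chrom: str
    position: int
    firing_time: float
    efficiency: float = 1.0


@dataclass(frozen=True)
class OriginProgram:
    """Origin positions, firing times/efficiencies plus global kinetics."""

    origins: tuple[Origin, ...]
    fork_velocity: float
    s_phase_duration: float

    def __post_init__(self):
        object.__setattr__(self, "origins", tuple(self.origins))
        if self.fork_velocity <= 0:
            raise ConfigError("fork_velocity must be > 0")
        if self.s_phase_duration <= 0:
            raise ConfigError("s_phase_duration must be > 0")
        for o in self.origins:
            if o.firing_time < 0:
                raise ConfigError(f"origin at {o.chrom}:{o.position} has negative firing time")
            if not 0.0 <= o.efficiency <= 1.0:
                raise ConfigError(f"origin at {o.chrom}:{o.position} has efficiency outside [0, 1]")

    def validate_for(self, genome: GenomeSpec) -> None:
        lengths = genome.lengths
        for o in self.origins:
            if o.chrom not in lengths:
                raise ConfigError(f"origin chromosome {o.chrom!r} not in genome")
            if not 0 <= o.position < lengths[o.chrom]:
                raise ConfigError(f"origin position {o.chrom}:{o.position} out of bounds")

    def by_chromosome(self) -> dict[str, list[tuple[int, Origin]]]:
        out: dict[str, list[tuple[int, Origin]]] = {}
        for i, o in enumerate(self.origins):
            out.setdefault(o.chrom, []).append((i, o))
        return out

    def rescaled(
        self,
        time_factor: float = 1.0,
        velocity_factor: float = 1.0,
        s_phase_duration: float | None = None,
    ) -> "OriginProgram":
        """Return a program with all T_i multiplied and v multiplied by the factors.

        Unless given explicitly, the new S-phase duration uses the bound
        ``t'(x) <= max(time_factor, 1/velocity_factor) * t(x)``, which keeps
        completion guaranteed for any slowdown.
        """
        if s_phase_duration is None:
            s_phase_duration = self.s_phase_duration * max(time_factor, 1.0 / velocity_factor)
        return OriginProgram(
            origins=tuple(
                Origin(o.chrom, o.position, o.firing_time * time_factor, o.efficiency)
                for o in self.origins
            ),
            fork_velocity=self.fork_velocity * velocity_factor,
            s_phase_duration=s_phase_duration,
        )


@dataclass
class ReplicationTimeline:
    """Replication time t(x) per chromosome plus the set of active origins.

    Deterministic mode evaluates the closed-form arrival-time minimum on
    demand; stochastic mode keeps the per-cell firing matrix so that
    ``times`` returns the across-cell mean replication time.
    """

    genome: GenomeSpec
    program: OriginProgram
    mode: str  # "deterministic" | "stochastic"
    active_origins: frozenset[int]  # indices into program.origins
    activation_frequency: dict[int, float] = field(default_factory=dict)
    _cell_firing: np.ndarray | None = None  # (n_cells, n_origins) bool

    def times(self, chrom: str, positions: Sequence[float] | np.ndarray) -> np.ndarray:
        x = np.asarray(positions, dtype=float)
        v = self.program.fork_velocity
        chrom_origins = self.program.by_chromosome().get(chrom, [])
        if not chrom_origins:
            raise ConfigError(f"chromosome {chrom!r} has no origins; replication cannot complete")
        if self.mode == "deterministic":
            t = np.full(x.shape, np.inf)
            for _, o in chrom_origins:
                np.minimum(t, o.firing_time + np.abs(x - o.position) / v, out=t)
            return t
        assert self._cell_firing is not None
        idx = np.array([i for i, _ in chrom_origins])
        arrivals = np.stack(
            [o.firing_time + np.abs(x - o.position) / v for _, o in chrom_origins]
        )  # (n_origins_chrom, n_pos)
        fired = self._cell_firing[:, idx]  # (n_cells, n_origins_chrom)
        acc = np.zeros(x.shape)
        for cell in range(fired.shape[0]):
            acc += np.min(arrivals[fired[cell]], axis=0)
        return acc / fired.shape[0]

    def max_time(self) -> float:
        """Largest replication time on any chromosome.

        Deterministic t(x) is a min of V-shaped functions with slopes
        +-1/v, so every local maximum sits either at a chromosome end or
        at a pairwise fork-crossing point; evaluating those candidates
        is exact.  Stochastic mode falls back to a dense grid.
        """
        out = 0.0
        v = self.program.fork_velocity
        for chrom, length in self.genome.chromosomes:
            items = self.program.by_chromosome().get(chrom, [])
            if self.mode == "deterministic":
                candidates = [0.0, float(length - 1)]
                for a in range(len(items)):
                    _, oa = items[a]
                    candidates.append(float(oa.position))
                    for b in range(a + 1, len(items)):
                        _, ob = items[b]
                        mid = (oa.position + ob.position) / 2
                        half = v * (ob.firing_time - oa.firing_time) / 2
                        candidates.append(float(np.clip(mid + half, 0.0, length - 1)))
                        candidates.append(float(np.clip(mid - half, 0.0, length - 1)))
                out = max(out, float(self.times(chrom, candidates).max()))
            else:
                grid = np.linspace(0, length - 1, min(length, 2048))
                out = max(out, float(self.times(chrom, grid).max()))
        return out


@dataclass
class AbundanceTrack:
    """Expected population DNA abundance A(x) in [1, 2] on a position grid."""

    genome: GenomeSpec
    positions: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, vals in self.values.items():
            if np.any(vals < 1.0 - 1e-9) or np.any(vals > 2.0 + 1e-9):
                raise ConfigError(f"abundance outside [1, 2] on chromosome {chrom!r}")

    def at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Linear interpolation of A at arbitrary coordinates."""
        return np.interp(
            np.asarray(positions, dtype=float), self.positions[chrom], self.values[chrom]
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_timeline(
    genome: GenomeSpec,
    program: OriginProgram,
    mode: str = "deterministic",
    seed: int | None = None,
    n_cells: int = 500,
    max_redraws: int = 1000,
) -> ReplicationTimeline:
    """Run the fork-progression model.

    Deterministic mode: ``t(x)`` is the arrival-time minimum over all
    origins of the chromosome; an origin is *active* iff no fork from
    another origin reaches its locus strictly before its firing time
    (arrival exactly at ``T_i`` counts as active).

    Stochastic mode: for each of ``n_cells`` simulated cells every
    origin fires independently with probability ``q_i``; chromosomes in
    which no origin fired are re-drawn (up to ``max_redraws`` rounds).
    ``times`` then reports the across-cell mean; ``active_origins``
    holds origins whose per-cell activation frequency is >= 0.5, with
    the full frequency table in ``activation_frequency``.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ConfigError(f"unknown mode {mode!r}")
    program.validate_for(genome)
    by_chrom = program.by_chromosome()
    for chrom, _ in genome.chromosomes:
        if mode == "deterministic" and not by_chrom.get(chrom):
            raise ConfigError(
                f"chromosome {chrom!r} has no origins; deterministic replication cannot complete"
            )

    if mode == "deterministic":
        v = program.fork_velocity
        active: set[int] = set()
        for chrom, items in by_chrom.items():
            for i, o in items:
                foreign = min(
                    (
                        p.firing_time + abs(o.position - p.position) / v
                        for j, p in items
                        if j != i
                    ),
                    default=np.inf,
                )
                if not foreign < o.firing_time:  # tie -> active
                    active.add(i)
        return ReplicationTimeline(genome, program, mode, frozenset(active))

    if seed is None:
        raise ConfigError("stochastic mode requires a seed")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_origins = len(program.origins)
    q = np.array([o.efficiency for o in program.origins])
    fired = rng.random((n_cells, n_origins)) < q

    # re-draw chromosomes where no origin fired in a given cell
    for chrom, _ in genome.chromosomes:
        idx = np.array([i for i, _ in by_chrom.get(chrom, [])], dtype=int)
        if idx.size == 0:
            continue
        if q[idx].max() <= 0.0:
            raise ConfigError(f"chromosome {chrom!r}: all origin efficiencies are 0")
        for _ in range(max_redraws):
            empty = ~fired[:, idx].any(axis=1)
            if not empty.any():
                break
            fired[np.ix_(empty, idx)] = rng.random((int(empty.sum()), idx.size)) < q[idx]
        else:
            raise ConfigError(f"chromosome {chrom!r}: could not obtain a fired origin per cell")

    # per-cell activity: fired and not passively replicated within that cell
    v = program.fork_velocity
    freq = {}
    for chrom, items in by_chrom.items():
        idx = np.array([i for i, _ in items], dtype=int)
        pos = np.array([o.position for _, o in items], dtype=float)
        t0 = np.array([o.firing_time for _, o in items], dtype=float)
        arrivals = t0[:, None] + np.abs(pos[None, :] - pos[:, None]) / v  # from j to i: [j, i]
        sub = fired[:, idx]
        for k, i in enumerate(idx):
            act = 0
            for cell in range(n_cells):
                if not sub[cell, k]:
                    continue
                others = sub[cell].copy()
                others[k] = False
                if others.any():
                    foreign = arrivals[others, k].min()
                    if foreign < t0[k]:
                        continue
                act += 1
            freq[int(i)] = act / n_cells
    active = frozenset(i for i, f in freq.items() if f >= 0.5)
    return ReplicationTimeline(genome, program, mode, active, freq, fired)


def population_abundance(
    timeline: ReplicationTimeline,
    t_s: float | None = None,
    positions: Mapping[str, np.ndarray] | None = None,
    grid_step: int = 1000,
) -> AbundanceTrack:
    """Expected DNA abundance of a sorted asynchronous S-phase population.

    ``A(x) = 2 - t(x)/T_S``: a locus replicated at t=0 is duplicated in
    every sampled cell (A=2) while a locus replicated at the very end of
    S phase is single-copy in almost all (A -> 1).

    Raises if any evaluated locus has ``t(x) > T_S``.
    """
    if t_s is None:
        t_s = timeline.program.s_phase_duration
    if positions is None:
        positions = {
            chrom: np.arange(0, length, grid_step, dtype=float)
            for chrom, length in timeline.genome.chromosomes
        }
    pos_out: dict[str, np.ndarray] = {}
    val_out: dict[str, np.ndarray] = {}
    for chrom, x in positions.items():
        x = np.asarray(x, dtype=float)
        t = timeline.times(chrom, x)
        if np.any(t > t_s + 1e-9):
            raise ConfigError(
                f"replication time exceeds S-phase duration on {chrom!r} "
                f"(max t = {t.max():.3f} > T_S = {t_s:.3f})"
            )
        pos_out[chrom] = x
        val_out[chrom] = 2.0 - t / t_s
    return AbundanceTrack(timeline.genome, pos_out, val_out)


def _expected_weights(
    abundance_at: Callable[[str, np.ndarray], np.ndarray] | None,
    fragments: FragmentTable,
    length_bias: Callable[[np.ndarray], np.ndarray] | None,
) -> np.ndarray:
    df = fragments.df
    if abundance_at is None:
        a = np.ones(len(df))
    else:
        a = np.concatenate(
            [
                abundance_at(chrom, sub[["start", "end"]].mean(axis=1).to_numpy())
                for chrom, sub in df.groupby("chrom", sort=False)
            ]
        )
        # groupby(sort=False) preserves first-appearance order == table order
    if length_bias is not None:
        a = a * np.asarray(length_bias(df["length"].to_numpy().astype(float)), dtype=float)
    if np.any(a < 0):
        raise ConfigError("negative expected fragment weight (check length_bias)")
    total = a.sum()
    if total <= 0:
        raise ConfigError("all expected fragment weights are zero")
    return a / total


def _draw(rng: np.random.Generator, lam: np.ndarray, noise: str, nb_dispersion: float) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(lam)
    if noise == "negative_binomial":
        r = nb_dispersion
        p = r / (r + lam)
        return rng.negative_binomial(r, p)
    raise ConfigError(f"unknown noise model {noise!r}")


def simulate_count_matrix(
    abundance: AbundanceTrack,
    fragments: FragmentTable,
    depth: float,
    n_s: int = 1,
    n_control: int = 1,
    strain: str = "strain",
    length_bias: Callable[[np.ndarray], np.ndarray] | None = None,
    noise: str = "poisson",
    seed: int = 0,
    nb_dispersion: float = 10.0,
) -> CountMatrix:
    """Draw a fragments x experiments count matrix.

    S-phase columns have expectation proportional to
    ``A(midpoint) * length_bias(length)``; control (G1/G2) columns use a
    flat abundance with the same length bias.  Each column's expected
    total equals ``depth``.  Column seeds are spawned from ``seed`` in
    order: S replicates first, then controls.
    """
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    if len(fragments.df) == 0:
        raise ConfigError("empty fragment table")
    w_s = _expected_weights(abundance.at, fragments, length_bias)
    w_c = _expected_weights(None, fragments, length_bias)
    children = np.random.SeedSequence(seed).spawn(n_s + n_control)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for r in range(n_s):
        rng = np.random.default_rng(children[r])
        name = f"{strain}_S_{r}"
        cols[name] = _draw(rng, w_s * depth, noise, nb_dispersion)
        meta_rows.append({"experiment": name, "strain": strain, "gate": "S"})
    for r in range(n_control):
        rng = np.random.default_rng(children[n_s + r])
        name = f"{strain}_G1G2_{r}"
        cols[name] = _draw(rng, w_c * depth, noise, nb_dispersion)
        meta_rows.append({"experiment": name, "strain": strain, "gate": "G1G2"})
    values = pd.DataFrame(cols, index=fragments.df.index)
    meta = pd.DataFrame(meta_rows).set_index("experiment")
    meta["total_reads"] = values.sum(axis=0).astype(int)
    return CountMatrix(values=values, fragments=fragments, meta=meta)


def synth_counts(
    abundance: AbundanceTrack,
    fragments: FragmentTable,
    depth: float,
    length_bias: Callable[[np.ndarray], np.ndarray] | None = None,
    noise: str = "poisson",
    seed: int = 0,
    strain: str = "strain",
    nb_dispersion: float = 10.0,
) -> CountMatrix:
    """One S-phase column plus one flat-abundance G1/G2 control column."""
    return simulate_count_matrix(
        abundance,
        fragments,
        depth,
        n_s=1,
        n_control=1,
        strain=strain,
        length_bias=length_bias,
        noise=noise,
        seed=seed,
        nb_dispersion=nb_dispersion,
    )


# ---------------------------------------------------------------------------
# Random fixtures (genome + origin program generators)
# ---------------------------------------------------------------------------

def random_genome(
    chrom_lengths: Sequence[int] = (800_000, 1_200_000, 1_000_000),
    seed: int = 0,
    with_sequence: bool = True,
) -> GenomeSpec:
    """Uniform-composition random genome (GATC then occurs every ~256 bp)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    chroms = tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(chrom_lengths))
    sequences = None
    if with_sequence:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {
            name: rng.choice(alphabet, size=length).tobytes().decode("ascii")
            for name, length in chroms
        }
    return GenomeSpec(chromosomes=chroms, sequences=sequences)


def random_origin_program(
    genome: GenomeSpec,
    n_origins: int = 40,
    fork_velocity: float = 2000.0,
    max_firing_time: float = 50.0,
    min_spacing: int = 40_000,
    edge_margin: int = 40_000,
    efficiency_range: tuple[float, float] = (0.6, 1.0),
    early_fraction: float = 0.85,
    dormancy_gamma: tuple[float, float] = (0.1, 0.3),
    wake_slowdown: float = 4.0,
    position_jitter: float = 0.2,
    timing_wavelength: float = 2_500_000.0,
    seed: int = 0,
) -> OriginProgram:
    """Generate an origin program with early origins plus dormant candidates.

    Origin counts are apportioned to chromosomes proportionally to length
    (largest remainder).  A fraction ``early_fraction`` of each
    chromosome's origins are "early": laid out on a jittered lattice
    (roughly even spacing, jitter ``position_jitter`` of the lattice
    step).  Their firing times follow a smooth spatial timing field —
    a random-phase sinusoid of wavelength ``timing_wavelength`` spanning
    [0, max_firing_time] plus a little origin-level jitter — mimicking
    replication-timing domains: neighbouring origins fire at similar
    times, so timing variation shapes the profile's broad swells while
    the sharp local structure (peaks and the valleys between adjacent
    origins) is governed by fork travel.  The remainder
    are dormant candidates dropped near the centre of mid-sized
    inter-origin gaps (wide enough that the emerging peak survives
    smoothing, while the largest gaps — the deepest valleys — stay
    origin-free); each fires between the time a fork would reach it at
    the program's velocity and the time one would at velocity
    v / wake_slowdown,

        T_dormant = arr(v) + g * (arr(v / wake_slowdown) - arr(v)),
        g ~ U[dormancy_gamma),   arr(u) = min over flanks (T_f + d_f / u),

    so it is always passively replicated at full fork speed (g > 0) yet
    fires once forks slow by ``wake_slowdown`` (g < 1); small g keeps
    the crossing points of the emerging peak well away from the origin
    on both sides, so the peak is wide enough to survive smoothing.  This
    mirrors real dormant origins: licensed in origin-dense regions and
    normally hidden by passive replication.  Keeping the largest gaps
    free of dormant candidates lets the deepest valleys deepen further
    when forks slow instead of being rescued, while origin-dense regions
    gain new peaks — the two halves of the sharpening phenotype.
    ``s_phase_duration`` gets ~10% headroom above the slowest
    deterministic completion time so abundance stays in bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    total = genome.total_length
    quotas = {name: n_origins * length / total for name, length in genome.chromosomes}
    counts = {name: int(np.floor(q)) for name, q in quotas.items()}
    remainder = n_origins - sum(counts.values())
    for name in sorted(quotas, key=lambda n: quotas[n] - counts[n], reverse=True)[:remainder]:
        counts[name] += 1

    origins: list[Origin] = []
    for name, length in genome.chromosomes:
        k = max(1, counts[name])
        n_early = max(1, int(round(k * early_fraction)))
        n_late = k - n_early
        lo, hi = edge_margin, length - edge_margin
        step = (hi - lo) / n_early
        early: list[int] | None = None
        for _ in range(1000):
            cand = sorted(
                int(lo + (i + 0.5) * step + rng.uniform(-position_jitter, position_jitter) * step)
                for i in range(n_early)
            )
            if all(b - a >= min_spacing for a, b in zip(cand[:-1], cand[1:])):
                early = cand
                break
        if early is None:
            raise ConfigError(
                f"could not place {n_early} origins on {name} with spacing {min_spacing}"
            )
        phase = rng.uniform(0.0, 2 * np.pi)
        half = max_firing_time / 2.0
        early_times = {
            p: float(
                np.clip(
                    half
                    + 0.9 * half * np.sin(2 * np.pi * p / timing_wavelength + phase)
                    + rng.normal(0.0, 0.05 * max_firing_time),
                    0.0,
                    max_firing_time,
                )
            )
            for p in early
        }
        gaps = sorted((b - a, a, b) for a, b in zip(early[:-1], early[1:]))
        if n_late > len(gaps):
            raise ConfigError(
                f"not enough inter-origin gaps for {n_late} dormant candidates on {name}"
            )
        start = (len(gaps) - n_late) // 2  # mid-sized gaps
        late: dict[int, float] = {}
        for gap, a, b in gaps[start : start + n_late]:
            pos = int((a + b) / 2 + rng.uniform(-0.1, 0.1) * gap)
            arr_fast = min(
                early_times[a] + (pos - a) / fork_velocity,
                early_times[b] + (b - pos) / fork_velocity,
            )
            arr_slow = min(
                early_times[a] + wake_slowdown * (pos - a) / fork_velocity,
                early_times[b] + wake_slowdown * (b - pos) / fork_velocity,
            )
            gamma = rng.uniform(*dormancy_gamma)
            late[pos] = arr_fast + gamma * (arr_slow - arr_fast)
        times = {**early_times, **late}
        for p in sorted(times):
            origins.append(
                Origin(
                    chrom=name,
                    position=p,
                    firing_time=times[p],
                    efficiency=float(rng.uniform(*efficiency_range)),
                )
            )
    prog = OriginProgram(tuple(origins), fork_velocity, s_phase_duration=1.0)
    timeline = simulate_timeline(genome, prog, mode="deterministic")
    t_max = timeline.max_time()
    return OriginProgram(tuple(origins), fork_velocity, s_phase_duration=1.1 * t_max)
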