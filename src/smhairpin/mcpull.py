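"""Coarse-grained Monte Carlo pulling (MCP) of peptide dimers.

A Go-like C-alpha model: beads on chains with stiff harmonic bonds,
12-10 wells on native contacts (salt-bridge contacts at double depth) and
a soft-sphere repulsion between all remaining pairs.  Metropolis dynamics
with single-bead Gaussian displacement moves; two virtual springs are
attached to the pulling groups (the N-terminal beads of each chain) and
their anchors recede along the inter-group vector at a fixed velocity per
sweep, mimicking constant-speed retraction in a force-spectroscopy
experiment.  The recorded spring tension vs anchor separation is the
pulling trace, and the rupture force is the maximum tension reached
before the inter-chain contact fraction first falls below a break
threshold.

Energies are expressed in kBT at the reference temperature (298 K);
``PullConfig.temperature`` rescales the Metropolis acceptance accordingly
and sets the pN conversion of spring forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ROOM_TEMPERATURE_K, kbt
from .errors import AnalysisError, ParameterError

__all__ = [
    "Contact",
    "CGModel",
    "PullConfig",
    "PullingTrace",
    "energy",
    "mc_pull",
    "sample_equilibrium",
    "rupture_stats",
]

#: default harmonic bond stiffness, kBT/nm^2 (stiff but steppable)
BOND_K = 300.0
#: soft-sphere diameter (nm) and strength (kBT)
REP_SIGMA = 0.3
REP_EPS = 1.0
#: closest approach used to keep pair energies finite for overlapping beads
R_CLIP = 0.05
#: a contact counts as formed while r < CONTACT_BREAK_FACTOR * r0
CONTACT_BREAK_FACTOR = 1.5


@dataclass(frozen=True)
class Contact:
    i: int
    j: int
    r0: float          # native distance, nm
    depth: float       # well depth, kBT (salt bridges carry 2x already)
    cls: str           # 'intra' | 'inter' | 'saltbridge'


@dataclass
class CGModel:
    """C-alpha chains with native contacts and pulling groups."""

    coords: np.ndarray                    # (n, 3) nm
    chain_of: np.ndarray                  # (n,) chain id per bead
    bonds: list[tuple[int, int, float, float]]  # (i, j, rest nm, k kBT/nm^2)
    contacts: list[Contact]
    pulling_groups: tuple[int, int] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_of = np.asarray(self.chain_of)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError("coords must be (n, 3)")
        n = self.coords.shape[0]
        if self.chain_of.size != n:
            raise ParameterError("chain_of must have one entry per bead")
        for i, j, _, _ in self.bonds:
            if self.chain_of[i] != self.chain_of[j] or abs(i - j) != 1:
                raise ParameterError(
                    f"bond ({i},{j}) must connect consecutive beads of one chain")
        if self.pulling_groups is not None:
            a, b = self.pulling_groups
            if self.chain_of[a] == self.chain_of[b]:
                raise ParameterError("pulling groups must sit on distinct chains")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def inter_contacts(self) -> list[Contact]:
        return [c for c in self.contacts if c.cls in ("inter", "saltbridge")]


@dataclass(frozen=True)
class PullConfig:
    """Monte Carlo pulling run parameters."""

    k_spring: float = 60.0          # pN/nm
    velocity_v: float = 0.02        # nm of anchor separation per sweep
    temperature: float = ROOM_TEMPERATURE_K
    sweeps: int = 1200
    seed: int = 0
    step_size: float = 0.06         # nm, Gaussian move SD (~40% acceptance)
    contact_break_fraction: float = 0.25

    def __post_init__(self):
        if self.k_spring <= 0 or self.velocity_v <= 0:
            raise ParameterError("k_spring and velocity_v must be positive")
        if self.temperature <= 0 or self.sweeps <= 0 or self.step_size <= 0:
            raise ParameterError("temperature, sweeps and step_size must be positive")
        if not 0 < self.contact_break_fraction < 1:
            raise ParameterError("contact_break_fraction must be in (0, 1)")


@dataclass
class PullingTrace:
    """Per-sweep record of one pulling run."""

    sweep: np.ndarray
    anchor_separation: np.ndarray   # nm
    spring_force: np.ndarray        # pN
    inter_contact_fraction: np.ndarray
    rupture_force: float            # pN
    rupture_sweep: int | None
    accept_rate: float


# ---------------------------------------------------------------------------
# pair tables and energy
# ---------------------------------------------------------------------------

class _PairTables:
    """Precomputed per-bead interaction partners for O(n) local moves."""

    def __init__(self, model: CGModel):
        n = model.n_beads
        bonded = {(min(i, j), max(i, j)) for i, j, _, _ in model.bonds}
        contact_pairs = {(min(c.i, c.j), max(c.i, c.j)) for c in model.contacts}

        self.bond_partners = [[] for _ in range(n)]
        for i, j, r0, k in model.bonds:
            self.bond_partners[i].append((j, r0, k))
            self.bond_partners[j].append((i, r0, k))
        self.contact_partners = [[] for _ in range(n)]
        for c in model.contacts:
            self.contact_partners[c.i].append((c.j, c.r0, c.depth))
            self.contact_partners[c.j].append((c.i, c.r0, c.depth))
        self.rep_partners = []
        for i in range(n):
            excl = {i} | {p for p, _, _ in self.bond_partners[i]} \
                       | {p for p, _, _ in self.contact_partners[i]}
            self.rep_partners.append(
                np.array([j for j in range(n) if j not in excl], dtype=np.intp))
        # vectorized views
        self.bond_idx = [
            (np.array([p for p, _, _ in lst], dtype=np.intp),
             np.array([r for _, r, _ in lst]),
             np.array([k for _, _, k in lst])) for lst in self.bond_partners]
        self.con_idx = [
            (np.array([p for p, _, _ in lst], dtype=np.intp),
             np.array([r for _, r, _ in lst]),
             np.array([d for _, _, d in lst])) for lst in self.contact_partners]

        self.inter_i = np.array([c.i for c in model.inter_contacts], dtype=np.intp)
        self.inter_j = np.array([c.j for c in model.inter_contacts], dtype=np.intp)
        self.inter_r0 = np.array([c.r0 for c in model.inter_contacts])


def _pair_well(r, r0, depth):
    # 12-10 native-contact well: minimum -depth at r = r0
    rr = r0 / np.maximum(r, R_CLIP)
    return depth * (5.0 * rr ** 12 - 6.0 * rr ** 10)


def _repulsion(r):
    return REP_EPS * (REP_SIGMA / np.maximum(r, R_CLIP)) ** 12


def _local_energy(coords, b, pos, tables: _PairTables) -> float:
    e = 0.0
    idx, r0, k = tables.bond_idx[b]
    if idx.size:
        d = np.linalg.norm(coords[idx] - pos, axis=1)
        e += float(np.sum(0.5 * k * (d - r0) ** 2))
    idx, r0, depth = tables.con_idx[b]
    if idx.size:
        d = np.linalg.norm(coords[idx] - pos, axis=1)
        e += float(np.sum(_pair_well(d, r0, depth)))
    rep = tables.rep_partners[b]
    if rep.size:
        d = np.linalg.norm(coords[rep] - pos, axis=1)
        e += float(np.sum(_repulsion(d)))
    return e


def energy(model: CGModel, coords=None) -> float:
    """Total potential energy (kBT) of a configuration.

    Finite for any finite configuration: overlapping beads are clipped to a
    large but finite repulsion.
    """
    coords = model.coords if coords is None else np.asarray(coords, dtype=float)
    n = model.n_beads
    e = 0.0
    for i, j, r0, k in model.bonds:
        d = np.linalg.norm(coords[j] - coords[i])
        e += 0.5 * k * (d - r0) ** 2
    for c in model.contacts:
        d = np.linalg.norm(coords[c.j] - coords[c.i])
        e += float(_pair_well(d, c.r0, c.depth))
    bonded = {(min(i, j), max(i, j)) for i, j, _, _ in model.bonds}
    contact = {(min(c.i, c.j), max(c.i, c.j)) for c in model.contacts}
    ii, jj = np.triu_indices(n, k=1)
    mask = np.array([(a, b) not in bonded and (a, b) not in contact
                     for a, b in zip(ii, jj)])
    if np.any(mask):
        d = np.linalg.norm(coords[jj[mask]] - coords[ii[mask]], axis=1)
        e += float(np.sum(_repulsion(d)))
    return float(e)


# ---------------------------------------------------------------------------
# Metropolis engines
# ---------------------------------------------------------------------------

def _metropolis_sweeps(model, tables, coords, rng, n_sweeps, step, beta,
                       spring=None, on_sweep=None):
    """Run sweeps of single-bead Gaussian moves; optional spring term.

    ``spring`` = (k_int, anchors dict {bead: anchor position}); ``on_sweep``
    is called after each sweep.  Returns the acceptance count and attempts.
    """
    n = coords.shape[0]
    accepted = attempts = 0
    for sweep in range(n_sweeps):
        beads = rng.integers(0, n, size=n)
        disps = rng.normal(0.0, step, size=(n, 3))
        for b, disp in zip(beads, disps):
            old = coords[b].copy()
            new = old + disp
            de = _local_energy(coords, b, new, tables) \
                - _local_energy(coords, b, old, tables)
            if spring is not None and b in spring[1]:
                k_int = spring[0]
                anchor = spring[1][b]
                de += 0.5 * k_int * (np.sum((new - anchor) ** 2)
                                     - np.sum((old - anchor) ** 2))
            attempts += 1
            if de <= 0 or rng.random() < np.exp(-beta * de):
                coords[b] = new
                accepted += 1
        if on_sweep is not None:
            on_sweep(sweep, coords)
    return accepted, attempts


def mc_pull(model: CGModel, cfg: PullConfig) -> PullingTrace:
    """Constant-velocity virtual-spring pulling of a dimer model.

    Anchors start at the pulling-group positions and recede symmetrically
    along the inter-group vector by ``velocity_v``/sweep total.  The spring
    force recorded each sweep is k_spring times the mean extension of the
    two springs.  The run stops shortly after the rupture criterion (the
    inter-chain contact fraction dropping below
    ``contact_break_fraction``) is met.
    """
    if model.pulling_groups is None:
        raise ParameterError("model has no pulling groups")
    tables = _PairTables(model)
    coords = model.coords.copy()
    rng = np.random.default_rng(cfg.seed)
    beta = ROOM_TEMPERATURE_K / cfg.temperature  # energies are in kBT(298)
    kbt_ref = kbt(ROOM_TEMPERATURE_K)
    k_int = cfg.k_spring / kbt_ref               # kBT/nm^2

    ga, gb = model.pulling_groups
    u = coords[gb] - coords[ga]
    u = u / np.linalg.norm(u)
    anchor_a = coords[ga].copy()
    anchor_b = coords[gb].copy()

    sweeps, seps, forces, fracs = [], [], [], []
    rupture_sweep = None
    tail_after_rupture = 50

    def frac_formed(c):
        if tables.inter_i.size == 0:
            return 0.0
        d = np.linalg.norm(c[tables.inter_j] - c[tables.inter_i], axis=1)
        return float(np.mean(d < CONTACT_BREAK_FACTOR * tables.inter_r0))

    accepted = attempts = 0
    for sweep in range(cfg.sweeps):
        anchor_a -= u * (cfg.velocity_v / 2.0)
        anchor_b += u * (cfg.velocity_v / 2.0)
        spring = (k_int, {ga: anchor_a, gb: anchor_b})
        acc, att = _metropolis_sweeps(model, tables, coords, rng, 1,
                                      cfg.step_size, beta, spring=spring)
        accepted += acc
        attempts += att
        ext = 0.5 * (np.linalg.norm(coords[ga] - anchor_a)
                     + np.linalg.norm(coords[gb] - anchor_b))
        sweeps.append(sweep)
        seps.append(float(np.linalg.norm(anchor_b - anchor_a)))
        forces.append(cfg.k_spring * ext)
        frac = frac_formed(coords)
        fracs.append(frac)
        if rupture_sweep is None and frac < cfg.contact_break_fraction:
            rupture_sweep = sweep
        if rupture_sweep is not None and sweep >= rupture_sweep + tail_after_rupture:
            break

    forces = np.asarray(forces)
    if rupture_sweep is not None:
        rupture_force = float(forces[:rupture_sweep + 1].max()) \
            if rupture_sweep >= 0 else 0.0
    else:
        rupture_force = float(forces.max())
    return PullingTrace(
        sweep=np.asarray(sweeps), anchor_separation=np.asarray(seps),
        spring_force=forces, inter_contact_fraction=np.asarray(fracs),
        rupture_force=rupture_force, rupture_sweep=rupture_sweep,
        accept_rate=accepted / max(attempts, 1),
    )


def sample_equilibrium(model: CGModel, sweeps=2000, step_size=0.1,
                       temperature=ROOM_TEMPERATURE_K, seed=0, thin=10,
                       burn_in=200):
    """Plain Metropolis sampling with no springs (anchors frozen).

    Returns ``(samples, energies)``: bead coordinates every ``thin`` sweeps
    after ``burn_in`` and the total energy at those frames.  Used for
    detailed-balance checks of the move set against Boltzmann statistics.
    """
    tables = _PairTables(model)
    coords = model.coords.copy()
    rng = np.random.default_rng(seed)
    beta = ROOM_TEMPERATURE_K / temperature
    samples, energies = [], []

    def record(sweep, c):
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            samples.append(c.copy())
            energies.append(energy(model, c))

    _metropolis_sweeps(model, tables, coords, rng, sweeps, step_size, beta,
                       on_sweep=record)
    return np.asarray(samples), np.asarray(energies)


def rupture_stats(traces) -> tuple[float, float]:
    """Mean and sample SD of per-trace rupture forces (pN)."""
    forces = [t.rupture_force if isinstance(t, PullingTrace) else float(t)
              for t in traces]
    if len(forces) < 2:
        raise AnalysisError(f"need >= 2 traces, got {len(forces)}")
    return float(np.mean(forces)), float(np.std(forces, ddof=1))
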