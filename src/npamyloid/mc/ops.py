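"""Python-facing operations of the Monte Carlo simulator.

The heavy loops live in :mod:`npamyloid.mc.engine`; this module owns system
setup, the move-level API used by the test oracles, the replicate driver and
the surface-area-matched size sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..errors import DataError, PackingError
from . import engine
from .config import NanoparticleSpec, SimulationConfig, matched_np_counts

MOVE_NAMES = ("pivot", "crankshaft", "kink_jump", "translation")


class MCRandom:
    """Deterministic xoshiro256++ stream shared with the jitted kernels."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.state = engine.rng_new(np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF))

    def uniform(self) -> float:
        return engine.rng_uniform(self.state)

    def below(self, n: int) -> int:
        return engine.rng_below(self.state, n)


def minimum_image_distance(p1, p2, box_length: float):
    """Euclidean distance under the nearest periodic image (3D, cubic box)."""
    d = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    d -= box_length * np.round(d / box_length)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass
class MoveProposal:
    move_type: str
    chain: int
    beads: np.ndarray          # global bead indices, shape (m,)
    new_positions: np.ndarray  # shape (m, 3)


@dataclass
class BondChanges:
    broken: list[tuple[int, int]]
    formed: list[tuple[int, int]]

    @property
    def net(self) -> int:
        return len(self.formed) - len(self.broken)


@dataclass
class AggregateReport:
    """Cluster statistics of one replicate over the analysis window."""

    cluster_sizes: list[np.ndarray]
    mean_chains_per_aggregate: float
    replicate: int
    seed: int
    n_accepted: int = 0
    n_attempted: int = 0
    final_energy: float = 0.0
    max_energy_drift: float = 0.0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_attempted, 1)


class SystemState:
    """Mutable state of one simulation system (flat numpy arrays).

    ``positions`` are unwrapped; use :meth:`wrapped_positions` for in-box
    coordinates.  The hydrogen-bond registry is the symmetric pair list held
    in ``bond_partner``/``bond_count``.
    """

    def __init__(self, config: SimulationConfig, positions: np.ndarray,
                 np_centers: np.ndarray):
        self.config = config
        self.positions = positions
        self.np_centers = np_centers
        nps = config.nanoparticles
        self.np_radii = np.array([p.diameter / 2 for p in nps], dtype=float)
        self.np_eps = np.array(
            [p.effective_adsorption_energy(config.curvature_length)
             for p in nps], dtype=float)
        self.np_shell = np.array(
            [p.effective_shell_thickness(config.shell_curvature_length)
             for p in nps], dtype=float)
        if config.block_bonds_when_adsorbed:
            self.np_occ = np.array(
                [2 if p.diameter / 2 >= config.occlusion_radius else 1
                 for p in nps], dtype=np.int64)
        else:
            self.np_occ = np.zeros(len(nps), dtype=np.int64)
        n_beads = config.n_beads
        self.bond_partner = np.full(
            (n_beads, config.max_bonds_per_bead), -1, dtype=np.int64)
        self.bond_count = np.zeros(n_beads, dtype=np.int64)
        self.energy = 0.0
        self.step = 0
        self._setup_cells()
        self._ws = None

    # -- derived geometry -------------------------------------------------

    def _setup_cells(self):
        cfg = self.config
        rcut = max(cfg.hb_cutoff, cfg.bead_diameter)
        nc = int(cfg.box_length / rcut)
        if nc < 3:
            nc = 1  # single cell: neighbor scan degenerates to all-pairs
        self.nc = nc
        n_beads = cfg.n_beads
        self.cell_head = np.full(nc ** 3, -1, dtype=np.int64)
        self.cell_next = np.full(n_beads, -1, dtype=np.int64)
        self.cell_prev = np.full(n_beads, -1, dtype=np.int64)
        self.cell_of = np.zeros(n_beads, dtype=np.int64)
        engine.build_cells(self.positions, cfg.box_length, nc,
                           self.cell_head, self.cell_next, self.cell_prev,
                           self.cell_of)
        self._build_np_cells()

    def _build_np_cells(self):
        """Static map cell -> nanoparticles whose core+shell can reach it."""
        cfg = self.config
        nc = self.nc
        box = cfg.box_length
        n_np = len(cfg.nanoparticles)
        if n_np == 0:
            self.np_cell_count = np.zeros(nc ** 3, dtype=np.int64)
            self.np_cell_list = np.zeros((nc ** 3, 1), dtype=np.int64)
            return
        cell_w = box / nc
        half_diag = 0.5 * cell_w * math.sqrt(3.0)
        idx = np.arange(nc)
        centers = (idx + 0.5) * cell_w
        gx, gy, gz = np.meshgrid(centers, centers, centers, indexing="ij")
        cell_centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        lists: list[list[int]] = [[] for _ in range(nc ** 3)]
        for k in range(n_np):
            reach = self.np_radii[k] + self.np_shell[k] + half_diag
            d = cell_centers - self.np_centers[k]
            d -= box * np.round(d / box)
            hit = np.flatnonzero((d * d).sum(axis=1) <= reach * reach)
            for c in hit:
                lists[c].append(k)
        width = max(1, max(len(l) for l in lists))
        self.np_cell_count = np.array([len(l) for l in lists], dtype=np.int64)
        self.np_cell_list = np.zeros((nc ** 3, width), dtype=np.int64)
        for c, l in enumerate(lists):
            for t, k in enumerate(l):
                self.np_cell_list[c, t] = k

    def _workspace(self):
        if self._ws is None:
            cfg = self.config
            Lc = cfg.chain_length
            self._ws = dict(
                moved_idx=np.empty(Lc, dtype=np.int64),
                new_pos=np.empty((Lc, 3), dtype=np.float64),
                moved_flag=np.zeros(cfg.n_beads, dtype=np.bool_),
                breaks=np.empty((Lc * cfg.max_bonds_per_bead, 2),
                                dtype=np.int64),
                forms=np.empty((512, 2), dtype=np.int64),
                cand_d=np.empty(512, dtype=np.float64),
                cand_b=np.empty(512, dtype=np.int64),
                cand_j=np.empty(512, dtype=np.int64),
                dcnt=np.zeros(cfg.n_beads, dtype=np.int64),
                touched=np.empty(1200, dtype=np.int64),
                e_scratch=np.empty(Lc, dtype=np.float64),
            )
        return self._ws

    # -- views and checks -------------------------------------------------

    @property
    def chain_positions(self) -> np.ndarray:
        cfg = self.config
        return self.positions.reshape(cfg.n_chains, cfg.chain_length, 3)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.config.box_length)

    def bond_pairs(self) -> set[tuple[int, int]]:
        pairs = set()
        for b in range(self.config.n_beads):
            for t in range(self.bond_count[b]):
                p = int(self.bond_partner[b, t])
                pairs.add((min(b, p), max(b, p)))
        return pairs

    def recompute_energy(self) -> float:
        cfg = self.config
        return float(engine.full_energy_kernel(
            self.positions, cfg.eps_hb, self.bond_partner, self.bond_count,
            cfg.box_length, self.nc, self.np_cell_count, self.np_cell_list,
            self.np_centers[:, 0], self.np_centers[:, 1],
            self.np_centers[:, 2], self.np_radii, self.np_eps,
            self.np_shell, self.np_occ))

    def validate(self, tol: float = 1e-9) -> None:
        """Assert every structural invariant; raises AssertionError."""
        cfg = self.config
        box = cfg.box_length
        w = self.wrapped_positions()
        tree = cKDTree(np.mod(w, box), boxsize=box)
        pairs = tree.query_pairs(r=cfg.bead_diameter * (1 - 1e-9))
        for i, j in pairs:
            same = i // cfg.chain_length == j // cfg.chain_length
            assert same and abs(i - j) == 1, (
                f"excluded-volume violation between beads {i}, {j}")
        if len(cfg.nanoparticles):
            for k in range(len(cfg.nanoparticles)):
                d = minimum_image_distance(w, self.np_centers[k], box)
                assert (d >= self.np_radii[k] - tol).all(), (
                    f"bead inside nanoparticle {k}")
        cp = self.chain_positions
        lens = np.linalg.norm(np.diff(cp, axis=1), axis=2)
        assert np.allclose(lens, cfg.bond_length, atol=1e-6), "bond lengths"
        for b in range(cfg.n_beads):
            assert self.bond_count[b] <= cfg.max_bonds_per_bead
            for t in range(self.bond_count[b]):
                p = int(self.bond_partner[b, t])
                assert p // cfg.chain_length != b // cfg.chain_length, (
                    "intra-chain bond")
                assert b in self.bond_partner[p, :self.bond_count[p]], (
                    "asymmetric bond registry")
                d = minimum_image_distance(self.positions[b],
                                           self.positions[p], box)
                assert d <= cfg.hb_cutoff + tol, "over-stretched bond"

    def _np_xyz(self):
        return (self.np_centers[:, 0], self.np_centers[:, 1],
                self.np_centers[:, 2])


# ---------------------------------------------------------------------------
# System initialization
# ---------------------------------------------------------------------------


def _place_nanoparticles(config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    box = config.box_length
    nps = config.nanoparticles
    centers = np.zeros((len(nps), 3))
    for k, spec in enumerate(nps):
        placed = False
        for _ in range(20_000):
            c = rng.uniform(0, box, size=3)
            ok = True
            for k2 in range(k):
                d = minimum_image_distance(c, centers[k2], box)
                if d < spec.diameter / 2 + nps[k2].diameter / 2:
                    ok = False
                    break
            if ok:
                centers[k] = c
                placed = True
                break
        if not placed:
            raise PackingError(
                "density too high: cannot place nanoparticles without overlap",
                achieved_density=config.number_density)
    return centers


def _grow_chains(config: SimulationConfig, centers: np.ndarray,
                 radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    box = config.box_length
    Lc = config.chain_length
    bd = config.bead_diameter
    bl = config.bond_length
    n_beads = config.n_beads
    pos = np.zeros((n_beads, 3))
    for chain in range(config.n_chains):
        start = chain * Lc
        grown = False
        for _attempt in range(200):
            placed = start
            p0 = rng.uniform(0, box, size=3)
            # adjacency exclusion never applies to the first bead
            if _any_clash(p0, pos, placed, centers, radii, box, bd, None):
                continue
            pos[start] = p0
            placed = start + 1
            ok = True
            for j in range(1, Lc):
                found = False
                for _try in range(80):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    cand = pos[start + j - 1] + bl * v
                    if not _any_clash(cand, pos, placed, centers, radii, box,
                                      bd, start + j - 1):
                        pos[start + j] = cand
                        placed = start + j + 1
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if ok:
                grown = True
                break
        if not grown:
            raise PackingError(
                "density too high: self-avoiding chain placement failed "
                f"after growing {chain} of {config.n_chains} chains",
                achieved_density=chain / box ** 3)
    return pos


def _any_clash(p, pos, n_placed, centers, radii, box, bd, adjacent_idx):
    if len(centers):
        d = minimum_image_distance(centers, p, box)
        if (d < radii).any():
            return True
    if n_placed == 0:
        return False
    d = minimum_image_distance(pos[:n_placed], p, box)
    if adjacent_idx is not None and adjacent_idx < n_placed:
        d[adjacent_idx] = np.inf  # bonded neighbor sits exactly at bond_length
    return bool((d < bd * (1 - 1e-12)).any())


def _initial_bonds(state: SystemState) -> None:
    """Greedy nearest-first scan of all inter-chain pairs within the cutoff."""
    cfg = state.config
    if cfg.eps_hb <= 0:
        return
    box = cfg.box_length
    w = state.wrapped_positions()
    tree = cKDTree(w, boxsize=box)
    pairs = tree.query_pairs(r=cfg.hb_cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return
    ci = pairs // cfg.chain_length
    inter = ci[:, 0] != ci[:, 1]
    pairs = pairs[inter]
    if len(pairs) == 0:
        return
    d = minimum_image_distance(state.positions[pairs[:, 0]],
                               state.positions[pairs[:, 1]], box)
    occ = _occlusion_levels(state)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], d))
    maxb = cfg.max_bonds_per_bead
    for idx in order:
        i, j = int(pairs[idx, 0]), int(pairs[idx, 1])
        if (state.bond_count[i] < maxb - occ[i]
                and state.bond_count[j] < maxb - occ[j]):
            state.bond_partner[i, state.bond_count[i]] = j
            state.bond_count[i] += 1
            state.bond_partner[j, state.bond_count[j]] = i
            state.bond_count[j] += 1


def _adsorbed_mask(state: SystemState) -> np.ndarray:
    return _occlusion_levels(state) > 0


def _occlusion_levels(state: SystemState) -> np.ndarray:
    """Per-bead number of bonding faces occluded by nanoparticle shells."""
    cfg = state.config
    occ = np.zeros(cfg.n_beads, dtype=np.int64)
    for k in range(len(cfg.nanoparticles)):
        d = minimum_image_distance(state.positions, state.np_centers[k],
                                   cfg.box_length)
        in_shell = ((d >= state.np_radii[k])
                    & (d < state.np_radii[k] + state.np_shell[k]))
        occ[in_shell] = np.maximum(occ[in_shell], state.np_occ[k])
    return occ


def init_system(config: SimulationConfig, seed: int) -> SystemState:
    """Random nanoparticle placement + self-avoiding chain growth + bond scan.

    Deterministic for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    centers = _place_nanoparticles(config, rng)
    radii = np.array([p.diameter / 2 for p in config.nanoparticles])
    pos = _grow_chains(config, centers, radii, rng)
    state = SystemState(config, pos, centers)
    _initial_bonds(state)
    state.energy = state.recompute_energy()
    return state


# ---------------------------------------------------------------------------
# Move-level API
# ---------------------------------------------------------------------------


def _weights_cum(config: SimulationConfig) -> np.ndarray:
    return np.cumsum(np.asarray(config.move_weights, dtype=float))


def propose_move(state: SystemState, config: SimulationConfig,
                 rng: MCRandom) -> MoveProposal:
    ws = state._workspace()
    mtype, chain, n_moved = engine.propose_kernel(
        state.positions, config.n_chains, config.chain_length,
        config.bead_diameter, _weights_cum(config), rng.state,
        ws["moved_idx"], ws["new_pos"])
    return MoveProposal(
        move_type=MOVE_NAMES[mtype], chain=chain,
        beads=ws["moved_idx"][:n_moved].copy(),
        new_positions=ws["new_pos"][:n_moved].copy())


def evaluate_move(state: SystemState, proposal: MoveProposal,
                  config: SimulationConfig) -> tuple[float, BondChanges]:
    n_moved = len(proposal.beads)
    if n_moved == 0:
        return 0.0, BondChanges([], [])
    ws = state._workspace()
    ws["moved_idx"][:n_moved] = proposal.beads
    ws["new_pos"][:n_moved] = proposal.new_positions
    nx, ny, nz = state._np_xyz()
    dE, nb, nf, reject = engine.evaluate_kernel(
        state.positions, config.chain_length, config.box_length, state.nc,
        state.cell_head, state.cell_next,
        config.eps_hb, config.hb_cutoff, config.bead_diameter,
        config.max_bonds_per_bead,
        state.bond_partner, state.bond_count,
        state.np_cell_count, state.np_cell_list, nx, ny, nz,
        state.np_radii, state.np_eps, state.np_shell, state.np_occ,
        ws["moved_idx"], n_moved, ws["new_pos"],
        ws["moved_flag"], ws["breaks"], ws["forms"],
        ws["cand_d"], ws["cand_b"], ws["cand_j"], ws["dcnt"], ws["touched"],
        ws["e_scratch"])
    if reject:
        return float("inf"), BondChanges([], [])
    broken = [(int(ws["breaks"][k, 0]), int(ws["breaks"][k, 1]))
              for k in range(nb)]
    formed = [(int(ws["forms"][k, 0]), int(ws["forms"][k, 1]))
              for k in range(nf)]
    return float(dE), BondChanges(broken, formed)


def metropolis_accept(delta_energy: float, rng: MCRandom) -> bool:
    """Standard Metropolis criterion: accept with probability min(1, e^-dE)."""
    return bool(engine.metropolis_kernel(delta_energy, rng.state))


def apply_move(state: SystemState, proposal: MoveProposal,
               changes: BondChanges, delta_energy: float) -> None:
    n_moved = len(proposal.beads)
    ws = state._workspace()
    ws["moved_idx"][:n_moved] = proposal.beads
    ws["new_pos"][:n_moved] = proposal.new_positions
    nb = len(changes.broken)
    nf = len(changes.formed)
    for k, (a, b) in enumerate(changes.broken):
        ws["breaks"][k, 0] = a
        ws["breaks"][k, 1] = b
    for k, (a, b) in enumerate(changes.formed):
        ws["forms"][k, 0] = a
        ws["forms"][k, 1] = b
    engine.commit_kernel(
        state.positions, state.config.box_length, state.nc,
        state.cell_head, state.cell_next, state.cell_prev, state.cell_of,
        state.bond_partner, state.bond_count,
        ws["moved_idx"], n_moved, ws["new_pos"],
        ws["breaks"], nb, ws["forms"], nf)
    state.energy += delta_energy
    state.step += 1


# ---------------------------------------------------------------------------
# Clustering and runs
# ---------------------------------------------------------------------------


def cluster_chains(state: SystemState,
                   merge_np_contacts: bool | None = None) -> np.ndarray:
    """Sizes of chain aggregates (connected via shared inter-chain H-bonds).

    With ``merge_np_contacts`` chains adsorbed on the same nanoparticle are
    merged as well.  Sizes sum to n_chains; singletons count as aggregates of
    size one.
    """
    cfg = state.config
    if merge_np_contacts is None:
        merge_np_contacts = cfg.merge_np_contacts
    out = np.zeros(cfg.n_chains, dtype=np.int64)
    nx, ny, nz = state._np_xyz()
    k = engine.record_clusters(
        state.positions, state.bond_partner, state.bond_count,
        cfg.chain_length, cfg.n_chains, merge_np_contacts,
        cfg.box_length, state.nc, state.np_cell_count, state.np_cell_list,
        nx, ny, nz, state.np_radii, state.np_eps, state.np_shell, out)
    return out[:k].copy()


def run_simulation(config: SimulationConfig, replicate: int = 0,
                   check_energy: bool = False,
                   return_state: bool = False):
    """One replicate: relax, produce, collect cluster snapshots.

    Replicate r is seeded with ``config.seed + r`` (initial coordinates and
    move stream).  With ``check_energy`` the incrementally updated total
    energy is compared against a from-scratch recomputation every 1000 steps
    and the maximum drift is reported (and asserted < 1e-8 kT).
    """
    seed = config.seed + replicate
    state = init_system(config, seed)
    rng = MCRandom(seed ^ 0x5EED5EED)
    stride = config.snapshot_stride
    n_snap = (config.n_analysis_steps + stride - 1) // stride
    snap_sizes = np.zeros((n_snap, config.n_chains), dtype=np.int64)
    energy_io = np.array([state.energy])
    nx, ny, nz = state._np_xyz()
    n_accept, max_drift = engine.run_kernel(
        state.positions, config.n_chains, config.chain_length,
        config.box_length, state.nc,
        state.cell_head, state.cell_next, state.cell_prev, state.cell_of,
        config.eps_hb, config.hb_cutoff, config.bead_diameter,
        config.max_bonds_per_bead,
        _weights_cum(config), state.bond_partner, state.bond_count,
        state.np_cell_count, state.np_cell_list, nx, ny, nz,
        state.np_radii, state.np_eps, state.np_shell, state.np_occ,
        rng.state,
        config.n_relax_steps, config.n_production_steps,
        config.n_analysis_steps, stride, config.merge_np_contacts,
        1000 if check_energy else 0, energy_io, snap_sizes)
    state.energy = float(energy_io[0])
    n_attempted = config.n_relax_steps + config.n_production_steps
    state.step = n_attempted
    if check_energy and max_drift > 1e-8:
        raise AssertionError(
            f"energy bookkeeping drift {max_drift:.3e} kT exceeds 1e-8")
    sizes = [row[row > 0].copy() for row in snap_sizes]
    means = [config.n_chains / len(s) for s in sizes if len(s)]
    report = AggregateReport(
        cluster_sizes=sizes,
        mean_chains_per_aggregate=float(np.mean(means)),
        replicate=replicate, seed=seed,
        n_accepted=int(n_accept), n_attempted=n_attempted,
        final_energy=state.energy, max_energy_drift=float(max_drift))
    if return_state:
        return report, state
    return report


def run_replicates(config: SimulationConfig,
                   check_energy: bool = False) -> list[AggregateReport]:
    return [run_simulation(config, r, check_energy=check_energy)
            for r in range(config.n_replicates)]


def size_sweep(diameters, total_surface_area: float,
               base_config: SimulationConfig,
               np_kwargs: dict | None = None,
               progress=None) -> pd.DataFrame:
    """Surface-area-matched sweep over nanoparticle diameters.

    For each diameter d the NP count is round(A / (pi d^2)); a zero-NP
    control condition is always included (diameter reported as 0).  Each
    condition runs ``base_config.n_replicates`` replicates from distinct
    seeds.  Returns a long-format table (diameter, n_np, replicate,
    mean_chains_per_aggregate, seed).
    """
    diameters = list(diameters)
    if min(diameters) <= 0:
        raise DataError("diameters must be positive")
    counts = matched_np_counts(diameters, total_surface_area)
    for d, n in zip(diameters, counts):
        if n == 0:
            raise DataError(
                f"surface-area budget too small: diameter {d} rounds to "
                "zero nanoparticles")
    np_kwargs = np_kwargs or {}
    rows = []
    conditions = [(0.0, 0)] + list(zip(diameters, counts))
    for ci, (d, n) in enumerate(conditions):
        if n:
            cfg = base_config.with_nanoparticles(d, n, **np_kwargs)
        else:
            cfg = base_config.model_copy(update={"nanoparticles": []})
        cfg = cfg.model_copy(update={"seed": base_config.seed + 100_000 * ci})
        for r in range(cfg.n_replicates):
            rep = run_simulation(cfg, r)
            rows.append(dict(diameter=d, n_np=n, replicate=r, seed=rep.seed,
                             mean_chains_per_aggregate=(
                                 rep.mean_chains_per_aggregate)))
            if progress is not None:
                progress(d, n, r, rep)
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """diameter-level mean and sd of mean_chains_per_aggregate."""
    g = table.groupby(["diameter", "n_np"])["mean_chains_per_aggregate"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_chains", "std": "sd_chains",
                               "count": "n_replicates"})
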