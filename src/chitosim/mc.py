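"""Metropolis Monte Carlo driver.

One MC step = one pivot move plus N_t titration attempts:

* **Pivot move** — pick a glycosidic link uniformly, draw new (φ, ψ)
  uniformly from the link map's cutoff-restricted region, rigidly rotate
  the downstream segment and accept with min(1, e^{−ΔE}) where
  ΔE = ΔE_map + ΔE_LJ + ΔE_DH (k_BT).  Proposals are symmetric on the
  fixed restricted set, so the chain samples the Boltzmann distribution
  truncated at the map cutoff.

* **Titration move** — pick a titratable site uniformly, propose
  z → 1 − z and accept with min(1, e^{−ΔF}), ΔF from the semi-grand
  titration free energy (chemical potential + screened pair term
  including nearest neighbours).  On acceptance the monomer's charge
  flips and the PMF maps of its (up to) two adjacent links are swapped
  for the maps of the new link types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import Conformation, build_sequence
from .energetics import (
    ForceFieldParams,
    SolutionConditions,
    nonbonded_delta,
    nonbonded_energy,
    protonation_mu,
    titration_energy,
)
from .pmf_maps import GLCNAC, GLCNH3, MapLibrary


@dataclass
class SimulationConfig:
    dp: int = 50
    dd: float = 1.0
    pattern: str = "random"
    pH: float = 4.5
    c_s: float = 0.1
    temperature: float = 298.0
    params: ForceFieldParams = field(default_factory=ForceFieldParams)
    library: MapLibrary | None = None
    n_steps: int = 10_000
    titration_per_step: int | None = None  # default: N_t attempts per step
    seed: int = 0
    log_stride: int = 100
    frame_stride: int | None = None
    burn_in_fraction: float = 0.2
    electrostatics: bool = True
    sterics: bool = True
    titration: bool = True
    map_swapping: bool = True
    force_link_key: tuple | None = None
    initial_charges: str = "auto"  # auto | charged | neutral
    check_stride: int = 10_000
    track_coverage: bool = False

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def conditions(self) -> SolutionConditions:
        return SolutionConditions(
            pH=self.pH, c_s=self.c_s, temperature=self.temperature
        )


@dataclass
class ObservableLog:
    """Per-stride observables plus raw counters and optional site frames."""

    records: pd.DataFrame
    counters: dict
    frames: list = field(default_factory=list)
    frame_steps: list = field(default_factory=list)
    coverage: dict | None = None
    config: SimulationConfig | None = None

    @property
    def equilibration_index(self) -> int:
        n = len(self.records)
        frac = self.config.burn_in_fraction if self.config else 0.2
        return int(math.floor(n * frac))

    def equilibrated(self, column: str = "r_g") -> np.ndarray:
        return self.records[column].to_numpy()[self.equilibration_index:]

    def stationarity_ok(self, column: str = "r_g") -> bool:
        """First and last thirds of the retained series agree within 2
        combined standard errors (simple stationarity screen)."""
        x = self.equilibrated(column)
        third = len(x) // 3
        if third < 2:
            return False
        a, b = x[:third], x[-third:]
        se = math.hypot(a.std(ddof=1) / math.sqrt(third), b.std(ddof=1) / math.sqrt(third))
        return abs(a.mean() - b.mean()) <= 2.0 * se if se > 0 else True


class MCState:
    """Live simulation state: conformation, charges, per-link map keys,
    incremental energy caches and move counters."""

    def __init__(self, config: SimulationConfig):
        if config.library is None:
            raise ValueError("a MapLibrary is required")
        cfg = config
        self.config = cfg
        self.conditions = cfg.conditions
        self.rng = np.random.default_rng(cfg.seed)
        self.sequence = build_sequence(
            cfg.dp, cfg.dd, cfg.pattern, seed=cfg.seed
        )
        self._init_charges()
        self.link_keys = [self._link_key(i) for i in range(cfg.dp - 1)]
        # initial conformation: every link at its assigned map's global minimum
        from .pmf_maps import find_minima

        dih = np.empty((cfg.dp - 1, 2))
        cache = {}
        for i, key in enumerate(self.link_keys):
            if key not in cache:
                mins = find_minima(cfg.library.map_for_link(*key))
                cache[key] = mins[0][:2] if mins else (0.0, 0.0)
            dih[i] = cache[key]
        self.conformation = Conformation(cfg.dp, dih)
        self.counters = {
            "pivot_attempted": 0,
            "pivot_accepted": 0,
            "titration_attempted": 0,
            "titration_accepted": 0,
        }
        self.coverage = (
            {i: set() for i in range(cfg.dp - 1)} if cfg.track_coverage else None
        )
        self._warned_no_titratable = False
        self.refresh_energies()

    # -- setup ---------------------------------------------------------------
    def _init_charges(self):
        cfg = self.config
        mode = cfg.initial_charges
        if mode == "auto":
            mode = "charged" if cfg.pH < cfg.params.pk_i else "neutral"
        if mode == "charged":
            self.sequence.charges[self.sequence.is_glcn] = 1
        elif mode == "neutral":
            self.sequence.charges[:] = 0
        else:
            raise ValueError(f"unknown initial_charges {mode!r}")

    def _link_key(self, i: int) -> tuple:
        cfg = self.config
        if cfg.force_link_key is not None:
            return cfg.force_link_key
        if cfg.map_swapping:
            return self.sequence.link_key(i)
        # static maps: titratable monomers always use the charged-state map
        lab = [
            GLCNAC if not self.sequence.is_glcn[j] else GLCNH3
            for j in (i, i + 1)
        ]
        return tuple(lab)

    # -- energies ------------------------------------------------------------
    def map_energy_total(self) -> float:
        lib = self.config.library
        e = 0.0
        for i in range(self.config.dp - 1):
            m = lib.map_for_link(*self.link_keys[i])
            e += m.energy_scalar(*self.conformation.dihedrals[i])
        return e

    def refresh_energies(self):
        cfg = self.config
        self.e_map = self.map_energy_total()
        if cfg.sterics or cfg.electrostatics:
            e_lj, e_dh = nonbonded_energy(
                self.conformation.sites,
                self.sequence.charges,
                self.conditions,
                cfg.params,
            )
        else:
            e_lj = e_dh = 0.0
        self.e_lj = e_lj if cfg.sterics else 0.0
        self.e_dh = e_dh if cfg.electrostatics else 0.0

    def f_prot(self) -> float:
        if self.sequence.n_t == 0:
            return 0.0
        if not self.config.electrostatics:
            from .energetics import protonation_mu

            mu = protonation_mu(self.conditions.pH, self.config.params.pk_i)
            return mu * float(self.sequence.charges.sum())
        return titration_energy(
            self.conformation.sites,
            self.sequence.charges,
            self.conditions,
            self.config.params,
        )

    def consistency_check(self, tol: float = 1e-6):
        """Map-key assignment and cached-energy invariants."""
        for i in range(self.config.dp - 1):
            if self.link_keys[i] != self._link_key(i):
                raise RuntimeError(
                    f"link {i}: assigned map key {self.link_keys[i]} does not "
                    f"match monomer states {self._link_key(i)}"
                )
        e_map, e_lj, e_dh = self.e_map, self.e_lj, self.e_dh
        self.refresh_energies()
        drift = max(
            abs(e_map - self.e_map), abs(e_lj - self.e_lj), abs(e_dh - self.e_dh)
        )
        if drift > max(tol, 1e-9 * self.config.dp):
            raise RuntimeError(f"cached energies drifted by {drift:.3e} k_BT")


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def pivot_move(state: MCState, rng=None) -> bool:
    cfg = state.config
    rng = rng or state.rng
    conf = state.conformation
    n_links = cfg.dp - 1
    link = int(rng.integers(n_links))
    key = state.link_keys[link]
    region = cfg.library.region_for_link(*key)
    phi_new, psi_new = region.sample(rng)
    dmap = cfg.library.map_for_link(*key)
    phi_old, psi_old = conf.dihedrals[link]
    de_map = dmap.energy_scalar(phi_new, psi_new) - dmap.energy_scalar(
        phi_old, psi_old
    )

    state.counters["pivot_attempted"] += 1
    j = link + 1
    saved = (
        conf.rots[j:].copy(),
        conf.trans[j:].copy(),
        conf.sites[j:].copy(),
    )
    need_nonbonded = (cfg.sterics or cfg.electrostatics) and cfg.dp > 2
    sites_old = conf.sites.copy() if need_nonbonded else None
    conf.pivot_update(link, phi_new, psi_new)

    de_lj = de_dh = 0.0
    if need_nonbonded:
        charges = (
            state.sequence.charges if cfg.electrostatics
            else np.zeros(cfg.dp, dtype=np.int8)
        )
        de_lj, de_dh = nonbonded_delta(
            sites_old, conf.sites, link, charges, state.conditions, cfg.params
        )
        if not cfg.sterics:
            de_lj = 0.0

    de = de_map + de_lj + de_dh
    if not math.isfinite(de):
        raise RuntimeError(f"non-finite pivot energy change at link {link}")
    if de <= 0.0 or rng.random() < math.exp(-de):
        state.e_map += de_map
        state.e_lj += de_lj
        state.e_dh += de_dh
        state.counters["pivot_accepted"] += 1
        if state.coverage is not None:
            nb = region.shape[1]
            i_bin = int((phi_new % (2 * math.pi)) / (2 * math.pi) * region.shape[0])
            j_bin = int((psi_new % (2 * math.pi)) / (2 * math.pi) * nb)
            state.coverage[link].add(i_bin * nb + j_bin)
        return True
    conf.rots[j:], conf.trans[j:], conf.sites[j:] = saved
    conf.dihedrals[link] = (phi_old, psi_old)
    return False


def _bonded_swap_delta(state: MCState, site: int) -> float:
    """Map-energy change of the (≤2) adjacent links if the site's charge
    flips (used only when bonded energy is included in titration)."""
    cfg = state.config
    seq = state.sequence
    z_old = seq.charges[site]
    seq.charges[site] = 1 - z_old
    de = 0.0
    for link in (site - 1, site):
        if 0 <= link < cfg.dp - 1:
            new_key = state._link_key(link)
            if new_key != state.link_keys[link]:
                phi, psi = state.conformation.dihedrals[link]
                m_new = cfg.library.map_for_link(*new_key)
                m_old = cfg.library.map_for_link(*state.link_keys[link])
                de += m_new.energy_scalar(phi, psi) - m_old.energy_scalar(phi, psi)
    seq.charges[site] = z_old
    return de


def titration_move(state: MCState, rng=None) -> bool:
    cfg = state.config
    rng = rng or state.rng
    seq = state.sequence
    tit = seq.titratable_indices
    if tit.size == 0:
        if not state._warned_no_titratable:
            warnings.warn("no titratable sites: titration move skipped")
            state._warned_no_titratable = True
        return False
    site = int(tit[rng.integers(tit.size)])
    state.counters["titration_attempted"] += 1

    dz = 1 - 2 * int(seq.charges[site])
    mu = protonation_mu(state.conditions.pH, cfg.params.pk_i)
    de_dh_conf = 0.0
    if cfg.electrostatics:
        charges = seq.charges
        others = np.nonzero(charges)[0]
        others = others[others != site]
        pair_all = pair_nonadj = 0.0
        if others.size:
            d = np.linalg.norm(
                state.conformation.sites[others] - state.conformation.sites[site],
                axis=1,
            )
            u = state.conditions.lambda_b * np.exp(-state.conditions.kappa * d) / d
            pair_all = float(u.sum())
            adjacent = np.abs(others - site) == 1
            pair_nonadj = pair_all - float(u[adjacent].sum())
        if cfg.params.double_count_titration_pairs:
            pair_all *= 2.0
        df = dz * (mu + pair_all)
        de_dh_conf = dz * pair_nonadj
    else:
        df = dz * mu

    de_bonded = 0.0
    if cfg.params.include_bonded_in_titration:
        de_bonded = _bonded_swap_delta(state, site)
    df_total = df + de_bonded
    if not math.isfinite(df_total):
        raise RuntimeError(f"non-finite titration energy change at site {site}")
    if df_total <= 0.0 or rng.random() < math.exp(-df_total):
        z_old = int(seq.charges[site])
        seq.charges[site] = 1 - z_old
        # map swapping: reassign the adjacent links' maps
        for link in (site - 1, site):
            if 0 <= link < cfg.dp - 1:
                new_key = state._link_key(link)
                if new_key != state.link_keys[link]:
                    phi, psi = state.conformation.dihedrals[link]
                    m_new = cfg.library.map_for_link(*new_key)
                    m_old = cfg.library.map_for_link(*state.link_keys[link])
                    state.e_map += m_new.energy_scalar(phi, psi) - m_old.energy_scalar(phi, psi)
                    state.link_keys[link] = new_key
        # conformational DH book-keeping: charged-pair set changed
        state.e_dh += de_dh_conf
        state.counters["titration_accepted"] += 1
        return True
    return False


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run(config: SimulationConfig) -> ObservableLog:
    """Execute the schedule (1 pivot + N_t titration attempts per step)."""
    state = MCState(config)
    cfg = config
    n_tit = (
        0
        if not cfg.titration
        else (cfg.titration_per_step if cfg.titration_per_step is not None
              else state.sequence.n_t)
    )
    records = []
    frames = []
    frame_steps = []
    rng = state.rng
    for step in range(1, cfg.n_steps + 1):
        pivot_move(state, rng)
        for _ in range(n_tit):
            titration_move(state, rng)
        if step % cfg.log_stride == 0 or step == cfg.n_steps:
            sites = state.conformation.sites
            com = sites.mean(axis=0)
            r_g = math.sqrt(float(np.mean(np.sum((sites - com) ** 2, axis=1))))
            n_t = state.sequence.n_t
            alpha = (
                float(1.0 - state.sequence.charges.sum() / n_t) if n_t else math.nan
            )
            c = state.counters
            records.append(
                {
                    "step": step,
                    "r_g": r_g,
                    "r_ee": state.conformation.end_to_end,
                    "alpha": alpha,
                    "e_map": state.e_map,
                    "e_lj": state.e_lj,
                    "e_dh": state.e_dh,
                    "f_prot": state.f_prot(),
                    "pivot_attempted": c["pivot_attempted"],
                    "pivot_accepted": c["pivot_accepted"],
                    "titration_attempted": c["titration_attempted"],
                    "titration_accepted": c["titration_accepted"],
                }
            )
            if cfg.frame_stride and (step % cfg.frame_stride == 0):
                frames.append(sites.copy())
                frame_steps.append(step)
        if cfg.check_stride and step % cfg.check_stride == 0:
            state.consistency_check()

    coverage = None
    if state.coverage is not None:
        coverage = {}
        for i, visited in state.coverage.items():
            region = cfg.library.region_for_link(*state.link_keys[i])
            coverage[i] = len(visited & set(region.allowed_flat.tolist())) / max(
                region.bin_count, 1
            )
    log = ObservableLog(
        records=pd.DataFrame.from_records(records),
        counters=dict(state.counters),
        frames=frames,
        frame_steps=frame_steps,
        coverage=coverage,
        config=cfg,
    )
    log.final_state = state
    return log


def acceptance_report(log: ObservableLog) -> dict:
    """Move-type acceptance rates, overall and post-equilibration."""
    rec = log.records
    out = {}
    k = log.equilibration_index
    for move in ("pivot", "titration"):
        att = int(rec[f"{move}_attempted"].iloc[-1])
        acc = int(rec[f"{move}_accepted"].iloc[-1])
        out[f"{move}_attempted"] = att
        out[f"{move}_accepted"] = acc
        out[f"{move}_rate"] = acc / att if att else math.nan
        if 0 < k < len(rec):
            att_w = att - int(rec[f"{move}_attempted"].iloc[k - 1])
            acc_w = acc - int(rec[f"{move}_accepted"].iloc[k - 1])
        else:
            att_w, acc_w = att, acc
        out[f"{move}_rate_equilibrated"] = acc_w / att_w if att_w else math.nan
    return out
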