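"""Synthetic transient-editing experiments: cut/repair kinetics + qPCR readout.

During transient Cas9/gRNA expression a cell's target loci fall into three
pools: intact wild-type DNA (cuttable), intact but mutated DNA (repaired with
an indel, no longer cuttable, still amplifiable) and broken DNA (a standing
crop of unrepaired double-strand breaks, not amplifiable across the cut).
The population model is linear:

    d f_wt/dt     = -k f_wt + rho (1 - mu) f_broken
    d f_broken/dt =  k f_wt - rho f_broken
    d f_mut/dt    =  rho mu f_broken

with cutting rate ``k = k_cut * delivery_scale`` (delivery_scale models a
transformation-boosting treatment such as sonication, which raises both the
effective cutting rate and the observed Cas9 transcript level), repair rate
``rho`` and per-repair mutation probability ``mu``. Error-free repair
recycles molecules into the cuttable pool; mutated repair is absorbing.

The qPCR readout turns a population state into a long-format Ct table: the
cut-spanning amplicon only amplifies the ``f_wt + f_mut`` fraction, so its
test-group Ct rises by ``-log_(1+E)(q)`` cycles over the control baseline
(E is the per-cycle amplification efficiency; every printed-formula estimator
assumes E = 1). Independent Gaussian noise is added per well.

Defaults (k_cut 0.1/h, rho 0.2/h, mu 0.3, 48 h, Ct noise SD 0.2 cycles) keep
the broken fraction in the experimentally observable range; they are model
settings, not measured biological constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import CtRecord, Group, Role

CONSERVATION_TOL = 1e-8


@dataclass(frozen=True)
class CutRepairParams:
    """Rates of the three-pool cut/repair model (per hour) and run horizon."""

    k_cut: float = 0.1
    rho_repair: float = 0.2
    mu_mut: float = 0.3
    t_end: float = 48.0
    cas9_level: float = 1.0
    delivery_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.k_cut < 0 or self.rho_repair < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.mu_mut <= 1.0:
            raise ValueError("mu_mut must be in [0, 1]")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.cas9_level <= 0 or self.delivery_scale <= 0:
            raise ValueError("cas9_level and delivery_scale must be > 0")

    @property
    def k_effective(self) -> float:
        return self.k_cut * self.delivery_scale


@dataclass(frozen=True)
class CutRepairState:
    """Population fractions of the three DNA pools at time ``t`` (hours)."""

    t: float
    f_intact_wt: float
    f_mutant: float
    f_broken: float

    @property
    def amplifiable(self) -> float:
        """Fraction of template the cut-spanning amplicon can amplify."""
        return self.f_intact_wt + self.f_mutant


@dataclass(frozen=True)
class ReadoutParams:
    """qPCR readout model: baseline Ct, amplification efficiency, well noise."""

    ct_baseline: float = 22.0
    amp_efficiency: float = 1.0  # per-cycle gain is 1 + E
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.amp_efficiency <= 1.0:
            raise ValueError("amp_efficiency must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def _deriv(y: np.ndarray, k: float, rho: float, mu: float) -> np.ndarray:
    f_wt, f_mut, f_broken = y
    return np.array(
        [
            -k * f_wt + rho * (1.0 - mu) * f_broken,
            rho * mu * f_broken,
            k * f_wt - rho * f_broken,
        ]
    )


def simulate_kinetics(params: CutRepairParams, step: float = 0.05) -> list[CutRepairState]:
    """Integrate the cut/repair system from (1, 0, 0) with fixed-step RK4.

    The step must satisfy ``step <= 1/(k + rho)`` (explicit-integration
    stability guard); pool fractions are checked to sum to 1 within 1e-8 at
    every step and renormalised against roundoff drift.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    k, rho, mu = params.k_effective, params.rho_repair, params.mu_mut
    total_rate = k + rho
    if total_rate > 0 and step > 1.0 / total_rate:
        raise ValueError(
            f"step {step} exceeds the stability bound 1/(k+rho) = "
            f"{1.0 / total_rate:.6g}; use a smaller step"
        )
    y = np.array([1.0, 0.0, 0.0])
    states = [CutRepairState(0.0, 1.0, 0.0, 0.0)]
    t = 0.0
    n_steps = math.ceil(params.t_end / step - 1e-12) if params.t_end > 0 else 0
    for i in range(n_steps):
        h = min(step, params.t_end - t)
        k1 = _deriv(y, k, rho, mu)
        k2 = _deriv(y + 0.5 * h * k1, k, rho, mu)
        k3 = _deriv(y + 0.5 * h * k2, k, rho, mu)
        k4 = _deriv(y + h * k3, k, rho, mu)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        total = y.sum()
        if abs(total - 1.0) > CONSERVATION_TOL:
            raise RuntimeError(
                f"conservation violated at t={t + h:.4g}: pool sum {total!r}"
            )
        y = np.clip(y, 0.0, 1.0)
        y /= y.sum()
        t = min((i + 1) * step, params.t_end)
        states.append(CutRepairState(t, float(y[0]), float(y[1]), float(y[2])))
    return states


def kinetics_frame(states: Sequence[CutRepairState]) -> pd.DataFrame:
    """Tidy time-series table (t, f_intact_wt, f_mutant, f_broken)."""
    return pd.DataFrame(
        {
            "t": [s.t for s in states],
            "f_intact_wt": [s.f_intact_wt for s in states],
            "f_mutant": [s.f_mutant for s in states],
            "f_broken": [s.f_broken for s in states],
        }
    )


def simulate_ct_table(
    states: Mapping[str, CutRepairState],
    readout: ReadoutParams,
    cas9_level: float = 1.0,
    delivery_scale: float = 1.0,
    n_replicates: int = 3,
    condition: str = "",
    rng: np.random.Generator | None = None,
) -> list[CtRecord]:
    """Emit a full test+control in vivo Ct table for one or more targets.

    Test-group target wells sit ``-log_(1+E)(f_wt + f_mut)`` cycles above the
    control baseline (broken DNA does not amplify); reference wells and all
    control-group wells sit at the baseline; the Cas9 transcript well sits
    ``log_(1+E)(cas9_level * delivery_scale)`` cycles below its reference.
    Every well receives independent Gaussian noise of SD ``ct_noise_sd``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if cas9_level <= 0 or delivery_scale <= 0:
        raise ValueError("cas9_level and delivery_scale must be > 0")
    if rng is None:
        rng = np.random.default_rng(readout.seed)
    gain = math.log1p(readout.amp_efficiency)
    sd = readout.ct_noise_sd

    def noisy(ct: float) -> float:
        return ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)

    cas_ct = readout.ct_baseline - math.log(cas9_level * delivery_scale) / gain
    records: list[CtRecord] = []
    for target_id, state in states.items():
        q = state.amplifiable
        if q <= 0:
            raise ValueError(
                f"target {target_id}: no amplifiable template (f_wt + f_mut = {q})"
            )
        test_target_ct = readout.ct_baseline - math.log(q) / gain
        for rep in range(1, n_replicates + 1):
            base = dict(target_id=target_id, replicate=rep, condition=condition)
            sid_test = f"{target_id}.{condition or 'expt'}.test.r{rep}"
            sid_ctrl = f"{target_id}.{condition or 'expt'}.control.r{rep}"
            records += [
                CtRecord(sid_test, assay_id=f"{target_id}.amp", role=Role.TARGET_REGION,
                         group=Group.TEST, ct=noisy(test_target_ct), **base),
                CtRecord(sid_test, assay_id="ubiquitin", role=Role.GENOMIC_REFERENCE,
                         group=Group.TEST, ct=noisy(readout.ct_baseline), **base),
                CtRecord(sid_test, assay_id="cas9", role=Role.CAS9_TRANSCRIPT,
                         group=Group.TEST, ct=noisy(cas_ct), **base),
                CtRecord(sid_test, assay_id="ubiquitin", role=Role.TRANSCRIPT_REFERENCE,
                         group=Group.TEST, ct=noisy(readout.ct_baseline), **base),
                CtRecord(sid_ctrl, assay_id=f"{target_id}.amp", role=Role.TARGET_REGION,
                         group=Group.CONTROL, ct=noisy(readout.ct_baseline), **base),
                CtRecord(sid_ctrl, assay_id="ubiquitin", role=Role.GENOMIC_REFERENCE,
                         group=Group.CONTROL, ct=noisy(readout.ct_baseline), **base),
            ]
    return records


def simulate_experiment(
    design: Mapping[str, float] | Iterable[tuple[str, float]],
    cas9_level: float = 1.0,
    readout: ReadoutParams | None = None,
    n_replicates: int = 3,
    delivery_scale: float = 1.0,
    condition: str = "",
) -> list[CtRecord]:
    """Direct-fraction shortcut: emit a Ct table for given true broken fractions.

    ``design`` maps target ids to true broken fractions in [0, 1). Noiseless
    quantification of the output in canonical mode returns exactly these
    fractions, which makes this the ground-truth generator for estimator
    validation. Duplicate target ids are an error.
    """
    pairs = list(design.items()) if isinstance(design, Mapping) else list(design)
    seen: set[str] = set()
    states: dict[str, CutRepairState] = {}
    for target_id, fraction in pairs:
        if target_id in seen:
            raise ValueError(f"duplicate target_id {target_id!r}")
        seen.add(target_id)
        if not 0.0 <= fraction < 1.0:
            raise ValueError(
                f"target {target_id}: broken fraction must be in [0, 1), got {fraction}"
            )
        states[target_id] = CutRepairState(
            t=0.0, f_intact_wt=1.0 - fraction, f_mutant=0.0, f_broken=fraction
        )
    if readout is None:
        readout = ReadoutParams()
    return simulate_ct_table(
        states,
        readout,
        cas9_level=cas9_level,
        delivery_scale=delivery_scale,
        n_replicates=n_replicates,
        condition=condition,
    )
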