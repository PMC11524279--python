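"""Ct-based estimators of CRISPR/Cas9 cutting efficiency.

The in vivo assay quantifies broken target DNA by qPCR. Two amplicons are run
per genomic template: one spanning the predicted Cas9 cut site (broken
molecules fail to amplify there) and an internal reference that avoids it.
The double difference

    ddCt = (Ct_T - Ct_Tref) - (Ct_C - Ct_Cref)

between edited ("test") and wild-type ("control") plants measures the loss of
amplifiable template at the target amplicon; at perfect amplification
efficiency the intact fraction is ``2**-ddCt`` and the broken fraction
``1 - 2**-ddCt``. Cutting efficiency is the broken-DNA abundance divided by
Cas9 transcript abundance (a dCt against a reference transcript measured on
cDNA), so target sites remain comparable across transformations that deliver
unequal amounts of Cas9.

Two conventions for "broken-DNA abundance" are supported everywhere via
``mode``:

* ``canonical`` (default): the broken fraction ``1 - 2**-ddCt``, the quantity
  consistent with the companion in vitro estimator (a ddCt of 2 means ~75% of
  the template is broken);
* ``literal``: the raw relative abundance ``2**-ddCt`` of still-amplifiable
  template, i.e. the plain fold-change some relative-quantification protocols
  report directly.

The in vitro assay digests a purified amplicon with recombinant Cas9 + gRNA
and compares a cut-site-spanning amplicon against a reference amplicon on the
same product: efficiency = ``1 - 2**-(Ct_a - Ct_ref)``, the same closed form
as the canonical in vivo estimator.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

MODES = ("canonical", "literal")
PAIRINGS = ("mean_control", "per_replicate")


class Role(str, enum.Enum):
    """What a qPCR well measures."""

    TARGET_REGION = "target_region"
    GENOMIC_REFERENCE = "genomic_reference"
    CAS9_TRANSCRIPT = "cas9_transcript"
    TRANSCRIPT_REFERENCE = "transcript_reference"
    INVITRO_TARGET = "invitro_target"
    INVITRO_REFERENCE = "invitro_reference"


class Template(str, enum.Enum):
    GENOMIC_DNA = "genomic_dna"
    CDNA = "cdna"
    PURIFIED_DNA = "purified_dna"


class Group(str, enum.Enum):
    TEST = "test"
    CONTROL = "control"


#: the template each role must be measured on
ROLE_TEMPLATE: dict[Role, Template] = {
    Role.TARGET_REGION: Template.GENOMIC_DNA,
    Role.GENOMIC_REFERENCE: Template.GENOMIC_DNA,
    Role.CAS9_TRANSCRIPT: Template.CDNA,
    Role.TRANSCRIPT_REFERENCE: Template.CDNA,
    Role.INVITRO_TARGET: Template.PURIFIED_DNA,
    Role.INVITRO_REFERENCE: Template.PURIFIED_DNA,
}

IN_VIVO_ROLES = (
    Role.TARGET_REGION,
    Role.GENOMIC_REFERENCE,
    Role.CAS9_TRANSCRIPT,
    Role.TRANSCRIPT_REFERENCE,
)


class QuantError(ValueError):
    """Invalid input to a quantification routine."""


class UndeterminedCtError(QuantError):
    """A well required by a formula did not amplify (undetermined Ct)."""


class NormalizationError(QuantError):
    """Fold-normalisation impossible: no strictly positive efficiency.

    Carries the per-target results computed so far (without normalised
    values) so callers can still inspect them.
    """

    def __init__(self, message: str, results: list["TargetQuantResult"] | None = None):
        super().__init__(message)
        self.results = results or []


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well, with enough metadata to route it into the estimators.

    ``ct`` is the cycle-threshold value in PCR cycles; ``None`` marks an
    undetermined (non-amplifying) well — a missing Ct is never encoded as a
    number. ``template`` may be omitted and is then derived from ``role``.
    """

    sample_id: str
    target_id: str
    assay_id: str
    role: Role
    group: Group
    replicate: int
    ct: float | None
    template: Template | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "group", Group(self.group))
        expected = ROLE_TEMPLATE[self.role]
        if self.template is None:
            object.__setattr__(self, "template", expected)
        else:
            object.__setattr__(self, "template", Template(self.template))
            if self.template is not expected:
                raise QuantError(
                    f"role {self.role.value} requires template {expected.value}, "
                    f"got {self.template.value}"
                )
        if int(self.replicate) < 1:
            raise QuantError(f"replicate must be >= 1, got {self.replicate}")
        object.__setattr__(self, "replicate", int(self.replicate))
        if self.ct is not None:
            ct = float(self.ct)
            if not math.isfinite(ct) or ct <= 0:
                raise QuantError(
                    f"ct must be finite and > 0 (got {self.ct!r}); use None for an "
                    "undetermined well"
                )
            object.__setattr__(self, "ct", ct)


@dataclass(frozen=True)
class TargetQuantResult:
    """Per-target in vivo quantification summary.

    ``ddct`` is the mean double-difference across usable test replicates;
    ``intact_fraction`` is literally ``2**-ddct`` and ``broken_fraction``
    its complement, regardless of ``mode``. ``relative_efficiency`` is the
    mean of per-replicate (broken-abundance / Cas9-abundance) values in the
    active mode, and is what fold-normalisation acts on.
    """

    target_id: str
    mode: str
    ddct: float
    intact_fraction: float
    broken_fraction: float
    cas9_abundance: float
    relative_efficiency: float
    normalized_efficiency: float | None
    n_replicates: int
    efficiency_sd: float
    p_value: float | None = None
    condition: str = ""
    replicate_efficiencies: tuple[float, ...] = ()
    clamped: bool = False
    is_reference: bool = False


def _require_ct(value: float | None, label: str) -> float:
    if value is None:
        raise UndeterminedCtError(f"undetermined Ct for {label}")
    value = float(value)
    if not math.isfinite(value):
        raise QuantError(f"non-finite Ct for {label}: {value}")
    return value


def delta_delta_ct(
    ct_t: float, ct_t_inter: float, ct_c: float, ct_c_inter: float
) -> float:
    """Double Ct difference (test target - test ref) - (control target - control ref)."""
    return (
        _require_ct(ct_t, "test target well, Ct(T)")
        - _require_ct(ct_t_inter, "test internal-reference well, Ct(T-inter)")
        - _require_ct(ct_c, "control target well, Ct(C)")
        + _require_ct(ct_c_inter, "control internal-reference well, Ct(C-inter)")
    )


def broken_dna_abundance(
    ct_t: float,
    ct_t_inter: float,
    ct_c: float,
    ct_c_inter: float,
    mode: str = "canonical",
) -> float:
    """Broken-DNA abundance implied by four in vivo Ct values.

    ``canonical`` returns the broken fraction ``1 - 2**-ddCt``;
    ``literal`` returns the raw relative abundance ``2**-ddCt``.
    Use :func:`delta_delta_ct` to obtain the underlying ddCt itself.
    """
    if mode not in MODES:
        raise QuantError(f"mode must be one of {MODES}, got {mode!r}")
    ddct = delta_delta_ct(ct_t, ct_t_inter, ct_c, ct_c_inter)
    intact = 2.0 ** (-ddct)
    return intact if mode == "literal" else 1.0 - intact


def cas9_abundance(ct_cas: float, ct_inter: float) -> float:
    """Cas9 transcript abundance ``2**-(Ct_cas - Ct_ref)`` relative to a reference gene."""
    if ct_cas is None:
        raise UndeterminedCtError(
            "undetermined Ct for Cas9 transcript well: Cas9 is not expressed, "
            "so cutting efficiency is undefined (not zero)"
        )
    cas = _require_ct(ct_cas, "Cas9 transcript well, Ct(Cas)")
    ref = _require_ct(ct_inter, "transcript reference well, Ct(inter)")
    return 2.0 ** (-(cas - ref))


def relative_cutting_efficiency(broken: float, cas9: float) -> float:
    """Broken-DNA abundance normalised by Cas9 abundance (no reordering, no rescaling)."""
    if not (cas9 > 0):
        raise QuantError(f"Cas9 abundance must be > 0, got {cas9}")
    return broken / cas9


class InVitroEfficiency(NamedTuple):
    """Raw and [0, 1]-clamped in vitro digestion efficiency."""

    value: float
    clamped: float
    complete_digestion: bool = False


def in_vitro_efficiency(ct_a: float | None, ct_inter: float) -> InVitroEfficiency:
    """Digestion efficiency ``1 - 2**-(Ct_a - Ct_ref)`` of a purified amplicon.

    ``ct_a`` comes from the amplicon containing the target site, ``ct_inter``
    from an amplicon on the same product without it. An undetermined ``ct_a``
    means the cut-site amplicon never amplified: efficiency is reported as 1
    with ``complete_digestion`` set. A raw value < 0 (``ct_a`` earlier than
    the reference) is kept alongside the clamped copy.
    """
    ref = _require_ct(ct_inter, "reference amplicon well, Ct(inter)")
    if ct_a is None:
        logger.warning(
            "target amplicon did not amplify: reporting complete digestion (efficiency 1)"
        )
        return InVitroEfficiency(1.0, 1.0, complete_digestion=True)
    a = _require_ct(ct_a, "target amplicon well, Ct(a)")
    raw = 1.0 - 2.0 ** (-(a - ref))
    return InVitroEfficiency(raw, min(max(raw, 0.0), 1.0))


def normalize_to_lowest(efficiencies: Mapping[str, float]) -> dict[str, float]:
    """Divide every efficiency by the smallest so the weakest target reads 1.

    Order-preserving; exact ties for the minimum all map to 1. Values must be
    strictly positive — clamp or flag non-positive efficiencies first.
    """
    if not efficiencies:
        raise QuantError("cannot normalise an empty efficiency map")
    bad = {k: v for k, v in efficiencies.items() if not (v > 0)}
    if bad:
        raise QuantError(
            f"non-positive efficiencies {bad}: clamp/flag them before fold-normalisation"
        )
    lowest = min(efficiencies.values())
    return {k: v / lowest for k, v in efficiencies.items()}


def students_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided, equal-variance two-sample t-test.

    Degenerate zero-variance inputs are resolved deterministically: equal
    means give (0, 1), unequal means (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise QuantError("t-test needs at least one observation per group")
    pooled_var = 0.0
    if a.size > 1:
        pooled_var += a.var(ddof=1) * (a.size - 1)
    if b.size > 1:
        pooled_var += b.var(ddof=1) * (b.size - 1)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# experiment-level quantification


def _collect_wells(records: Iterable[CtRecord]):
    """Split validated in vivo records into control and test lookups."""
    control: dict[str, dict[Role, dict[int, float | None]]] = {}
    test: dict[tuple[str, str], dict[int, dict[Role, float | None]]] = {}
    for rec in records:
        if rec.role not in IN_VIVO_ROLES:
            continue
        if rec.group is Group.CONTROL:
            control.setdefault(rec.target_id, {}).setdefault(rec.role, {})[
                rec.replicate
            ] = rec.ct
        else:
            test.setdefault((rec.target_id, rec.condition), {}).setdefault(
                rec.replicate, {}
            )[rec.role] = rec.ct
    return control, test


def _control_ct(
    control: Mapping[Role, Mapping[int, float | None]],
    role: Role,
    pairing: str,
    replicate: int,
    target_id: str,
) -> float | None:
    wells = control.get(role, {})
    if pairing == "per_replicate":
        return wells.get(replicate)
    determined = [ct for ct in wells.values() if ct is not None]
    if not determined:
        return None
    return float(np.mean(determined))


def quantify_experiment(
    records: Iterable[CtRecord],
    mode: str = "canonical",
    pairing: str = "mean_control",
    clamp_floor: float = 1e-6,
    compare: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> list[TargetQuantResult]:
    """Quantify cutting efficiency for every target in a Ct table.

    For each target (and condition), one efficiency is computed per usable
    test replicate — ``mean_control`` (default) pairs every test replicate
    against the control-group mean Ct, ``per_replicate`` against the
    index-matched control replicate — then mean, SD and n are reported and
    the per-target mean efficiencies are fold-normalised to the lowest
    target within each condition. Replicates missing any of the four in vivo
    wells are dropped with a warning; a target with no usable replicate is
    excluded and flagged in the log.

    Negative mean efficiencies (noise-driven ddCt < 0) are clamped to
    ``clamp_floor`` for normalisation only, with ``clamped`` set on the
    result. If *every* target had to be clamped the experiment carries no
    usable signal and :class:`NormalizationError` is raised.

    ``compare=(cond_a, cond_b)`` attaches a per-target two-sample Student's
    t-test p-value between the per-replicate efficiencies of the two
    condition groups.
    """
    if mode not in MODES:
        raise QuantError(f"mode must be one of {MODES}, got {mode!r}")
    if pairing not in PAIRINGS:
        raise QuantError(f"pairing must be one of {PAIRINGS}, got {pairing!r}")
    records = list(records)
    control, test = _collect_wells(records)

    summaries: list[dict] = []
    for (target_id, condition), reps in test.items():
        ctrl = control.get(target_id)
        if not ctrl:
            logger.warning("target %s: no control wells; target excluded", target_id)
            continue
        ddcts, cas_dcts, effs = [], [], []
        for rep in sorted(reps):
            wells = reps[rep]
            missing = [r.value for r in IN_VIVO_ROLES if wells.get(r) is None]
            ct_c = _control_ct(ctrl, Role.TARGET_REGION, pairing, rep, target_id)
            ct_c_inter = _control_ct(
                ctrl, Role.GENOMIC_REFERENCE, pairing, rep, target_id
            )
            if ct_c is None or ct_c_inter is None:
                missing.append("control target/reference")
            if missing:
                logger.warning(
                    "target %s replicate %d dropped: missing/undetermined %s",
                    target_id,
                    rep,
                    ", ".join(missing),
                )
                continue
            ddct = delta_delta_ct(
                wells[Role.TARGET_REGION],
                wells[Role.GENOMIC_REFERENCE],
                ct_c,
                ct_c_inter,
            )
            intact = 2.0 ** (-ddct)
            broken = intact if mode == "literal" else 1.0 - intact
            cas_dct = wells[Role.CAS9_TRANSCRIPT] - wells[Role.TRANSCRIPT_REFERENCE]
            cas9 = 2.0 ** (-cas_dct)
            ddcts.append(ddct)
            cas_dcts.append(cas_dct)
            effs.append(relative_cutting_efficiency(broken, cas9))
        if not effs:
            logger.warning(
                "target %s: zero usable replicates; excluded from normalisation",
                target_id,
            )
            continue
        ddct_mean = float(np.mean(ddcts))
        intact_mean = 2.0 ** (-ddct_mean)
        summaries.append(
            dict(
                target_id=target_id,
                condition=condition,
                ddct=ddct_mean,
                intact_fraction=intact_mean,
                broken_fraction=1.0 - intact_mean,
                cas9_abundance=2.0 ** (-float(np.mean(cas_dcts))),
                relative_efficiency=float(np.mean(effs)),
                efficiency_sd=float(np.std(effs, ddof=1)) if len(effs) > 1 else 0.0,
                n_replicates=len(effs),
                replicate_efficiencies=tuple(effs),
            )
        )

    if not summaries:
        raise QuantError(
            "no usable replicates for any target: check that every test replicate "
            "has target_region, genomic_reference, cas9_transcript and "
            "transcript_reference wells and that control wells are present"
        )

    # fold-normalisation per condition, clamping non-positive means first
    by_condition: dict[str, list[dict]] = {}
    for s in summaries:
        by_condition.setdefault(s["condition"], []).append(s)
    for condition, items in by_condition.items():
        clamped_ids = []
        values = {}
        for s in items:
            v = s["relative_efficiency"]
            if not (v > clamp_floor):
                clamped_ids.append(s["target_id"])
                s["clamped"] = True
                v = clamp_floor
            values[s["target_id"]] = v
        if len(clamped_ids) == len(items):
            raise NormalizationError(
                f"condition {condition or '(default)'}: every target has a "
                f"non-positive efficiency (<= {clamp_floor}); nothing to normalise "
                "against",
                results=[_finalize(s, mode, None) for s in items],
            )
        if clamped_ids:
            logger.warning(
                "non-positive efficiencies clamped to %g for normalisation: %s",
                clamp_floor,
                ", ".join(clamped_ids),
            )
        normalized = normalize_to_lowest(values)
        lowest = min(values.values())
        reference_seen = False
        for s in items:
            s["normalized_efficiency"] = normalized[s["target_id"]]
            if not reference_seen and values[s["target_id"]] == lowest:
                s["is_reference"] = True
                reference_seen = True

    # between-condition significance on per-replicate efficiencies
    if compare is not None:
        cond_a, cond_b = compare
        effs_by = {
            (s["target_id"], s["condition"]): s["replicate_efficiencies"]
            for s in summaries
        }
        for s in summaries:
            if s["condition"] not in (cond_a, cond_b):
                continue
            a = effs_by.get((s["target_id"], cond_a))
            b = effs_by.get((s["target_id"], cond_b))
            if a and b:
                _, p = students_t(a, b)
                s["p_value"] = p

    return [_finalize(s, mode, s.get("normalized_efficiency")) for s in summaries]


def _finalize(s: dict, mode: str, normalized: float | None) -> TargetQuantResult:
    return TargetQuantResult(
        target_id=s["target_id"],
        mode=mode,
        ddct=s["ddct"],
        intact_fraction=s["intact_fraction"],
        broken_fraction=s["broken_fraction"],
        cas9_abundance=s["cas9_abundance"],
        relative_efficiency=s["relative_efficiency"],
        normalized_efficiency=normalized,
        n_replicates=s["n_replicates"],
        efficiency_sd=s["efficiency_sd"],
        p_value=s.get("p_value"),
        condition=s["condition"],
        replicate_efficiencies=s["replicate_efficiencies"],
        clamped=s.get("clamped", False),
        is_reference=s.get("is_reference", False),
    )


@dataclass(frozen=True)
class InVitroResult:
    """Per-target summary of the in vitro digestion assay."""

    target_id: str
    efficiency: float
    efficiency_clamped: float
    sd: float
    n_replicates: int
    complete_digestion: bool


def quantify_invitro(records: Iterable[CtRecord]) -> list[InVitroResult]:
    """Aggregate in vitro digestion efficiencies per target.

    Wells are paired within (target, replicate); a replicate lacking the
    reference amplicon is dropped with a warning, while an undetermined
    target-amplicon Ct counts as complete digestion (efficiency 1).
    """
    wells: dict[str, dict[int, dict[Role, float | None]]] = {}
    for rec in records:
        if rec.role in (Role.INVITRO_TARGET, Role.INVITRO_REFERENCE):
            wells.setdefault(rec.target_id, {}).setdefault(rec.replicate, {})[
                rec.role
            ] = rec.ct
    results = []
    for target_id, reps in wells.items():
        raws, clamps, complete = [], [], False
        for rep in sorted(reps):
            pair = reps[rep]
            if Role.INVITRO_REFERENCE not in pair or pair[Role.INVITRO_REFERENCE] is None:
                logger.warning(
                    "target %s replicate %d dropped: missing/undetermined reference "
                    "amplicon",
                    target_id,
                    rep,
                )
                continue
            if Role.INVITRO_TARGET not in pair:
                logger.warning(
                    "target %s replicate %d dropped: missing target amplicon well",
                    target_id,
                    rep,
                )
                continue
            eff = in_vitro_efficiency(pair[Role.INVITRO_TARGET], pair[Role.INVITRO_REFERENCE])
            raws.append(eff.value)
            clamps.append(eff.clamped)
            complete = complete or eff.complete_digestion
        if not raws:
            logger.warning("target %s: zero usable in vitro replicates", target_id)
            continue
        results.append(
            InVitroResult(
                target_id=target_id,
                efficiency=float(np.mean(raws)),
                efficiency_clamped=float(np.mean(clamps)),
                sd=float(np.std(raws, ddof=1)) if len(raws) > 1 else 0.0,
                n_replicates=len(raws),
                complete_digestion=complete,
            )
        )
    return results


def compare_experiments(
    records_a: Iterable[CtRecord],
    records_b: Iterable[CtRecord],
    mode: str = "canonical",
    pairing: str = "mean_control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-target treatment/control comparison of two quantified Ct tables.

    ``records_a`` is the treatment experiment, ``records_b`` the control.
    Ratios are reported for the mean relative efficiency, the broken-DNA
    fraction and the Cas9 abundance, with a two-sample Student's t-test on
    the per-replicate efficiencies.
    """
    res_a = {r.target_id: r for r in quantify_experiment(records_a, mode=mode, pairing=pairing)}
    res_b = {r.target_id: r for r in quantify_experiment(records_b, mode=mode, pairing=pairing)}
    rows = []
    for target_id, ra in res_a.items():
        rb = res_b.get(target_id)
        if rb is None:
            logger.warning("target %s present only in the treatment table", target_id)
            continue
        t, p = students_t(ra.replicate_efficiencies, rb.replicate_efficiencies)
        rows.append(
            {
                "target_id": target_id,
                "efficiency_treatment": ra.relative_efficiency,
                "efficiency_control": rb.relative_efficiency,
                "efficiency_ratio": ra.relative_efficiency / rb.relative_efficiency
                if rb.relative_efficiency != 0
                else math.nan,
                "broken_treatment": ra.broken_fraction,
                "broken_control": rb.broken_fraction,
                "broken_ratio": ra.broken_fraction / rb.broken_fraction
                if rb.broken_fraction != 0
                else math.nan,
                "cas9_treatment": ra.cas9_abundance,
                "cas9_control": rb.cas9_abundance,
                "cas9_ratio": ra.cas9_abundance / rb.cas9_abundance,
                "t_stat": t,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
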