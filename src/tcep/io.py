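"""File formats: long-format Ct CSV, results CSV, FASTA, BED6, config.

The Ct table dialect is one row per well with the exact header
``sample_id,target_id,assay_id,role,template,group,condition,replicate,ct``;
an empty ``ct`` field marks an undetermined (non-amplifying) well and
round-trips losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .guides import TargetSite
from .quant import CtRecord, InVitroResult, QuantError, TargetQuantResult

logger = logging.getLogger(__name__)

CT_COLUMNS = [
    "sample_id",
    "target_id",
    "assay_id",
    "role",
    "template",
    "group",
    "condition",
    "replicate",
    "ct",
]

RESULT_COLUMNS = [
    "target_id",
    "mode",
    "ddct",
    "broken_fraction",
    "cas9_abundance",
    "relative_efficiency",
    "normalized_efficiency",
    "sd",
    "n",
    "p_value",
]


def read_ct_csv(path: str | Path) -> list[CtRecord]:
    """Read a long-format Ct table, validating the schema row by row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != CT_COLUMNS:
        raise QuantError(
            f"{path}: bad Ct CSV header {list(df.columns)}; expected {CT_COLUMNS}"
        )
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            ct_raw = row.ct.strip()
            records.append(
                CtRecord(
                    sample_id=row.sample_id,
                    target_id=row.target_id,
                    assay_id=row.assay_id,
                    role=row.role,
                    template=row.template or None,
                    group=row.group,
                    condition=row.condition,
                    replicate=int(row.replicate),
                    ct=float(ct_raw) if ct_raw else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise QuantError(f"{path}: line {idx}: {exc}") from exc
    return records


def write_ct_csv(records: Iterable[CtRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "target_id": r.target_id,
            "assay_id": r.assay_id,
            "role": r.role.value,
            "template": r.template.value,
            "group": r.group.value,
            "condition": r.condition,
            "replicate": r.replicate,
            "ct": "" if r.ct is None else repr(r.ct),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CT_COLUMNS).to_csv(path, index=False)


def write_results_csv(results: Sequence[TargetQuantResult], path: str | Path) -> None:
    """Write per-target quantification results.

    A ``condition`` column is appended only when more than one condition
    label is present.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "target_id": r.target_id,
                "mode": r.mode,
                "ddct": r.ddct,
                "broken_fraction": r.broken_fraction,
                "cas9_abundance": r.cas9_abundance,
                "relative_efficiency": r.relative_efficiency,
                "normalized_efficiency": r.normalized_efficiency,
                "sd": r.efficiency_sd,
                "n": r.n_replicates,
                "p_value": r.p_value,
                "condition": r.condition,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["condition"])
    if df["condition"].nunique() <= 1:
        df = df[RESULT_COLUMNS]
    df.to_csv(path, index=False)


def write_invitro_csv(results: Sequence[InVitroResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "efficiency": r.efficiency,
                "efficiency_clamped": r.efficiency_clamped,
                "sd": r.sd,
                "n": r.n_replicates,
                "complete_digestion": r.complete_digestion,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into (id, sequence) pairs; empty files are errors."""
    try:
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not entries:
        raise ValueError(f"{path}: no FASTA records found")
    for seq_id, seq in entries:
        if not seq:
            raise ValueError(f"{path}: record {seq_id!r} has an empty sequence")
    return entries


def write_bed(sites: Sequence[TargetSite], path: str | Path) -> None:
    """BED6 over the full spacer+PAM footprint, name = spacer."""
    with open(path, "w") as fh:
        for site in sites:
            start, end = site.footprint
            fh.write(
                f"{site.seq_id}\t{start}\t{end}\t{site.spacer}\t0\t{site.strand}\n"
            )


def write_sites_table(sites: Sequence[TargetSite], path: str | Path) -> None:
    """Tab-separated site detail table including the inter-base cut position."""
    pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "strand": s.strand,
                "pam_start": s.pam_start,
                "cut_pos": s.cut_pos,
                "footprint_start": s.footprint[0],
                "footprint_end": s.footprint[1],
                "spacer": s.spacer,
                "pam": s.pam,
            }
            for s in sites
        ],
        columns=[
            "seq_id",
            "strand",
            "pam_start",
            "cut_pos",
            "footprint_start",
            "footprint_end",
            "spacer",
            "pam",
        ],
    ).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML (or plain ``key: value``) run-configuration file."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of key: value pairs")
    return cfg
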