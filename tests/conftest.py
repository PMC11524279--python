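import pytest

from tcep.quant import CtRecord, Group, Role


def make_invivo_records(
    targets: dict[str, tuple[float, float]],
    n_replicates: int = 1,
    baseline: float = 20.0,
    condition: str = "",
) -> list[CtRecord]:
    """Hand-built noiseless in vivo Ct table.

    ``targets`` maps target_id -> (ddct, cas9_dct): the test target well sits
    ``ddct`` cycles above baseline and the Cas9 well ``cas9_dct`` cycles above
    its reference; every other well sits at the baseline.
    """
    records = []
    for target_id, (ddct, cas9_dct) in targets.items():
        for rep in range(1, n_replicates + 1):
            common = dict(target_id=target_id, replicate=rep, condition=condition)
            records += [
                CtRecord(f"{target_id}.test.r{rep}", assay_id=target_id,
                         role=Role.TARGET_REGION, group=Group.TEST,
                         ct=baseline + ddct, **common),
                CtRecord(f"{target_id}.test.r{rep}", assay_id="ubq",
                         role=Role.GENOMIC_REFERENCE, group=Group.TEST,
                         ct=baseline, **common),
                CtRecord(f"{target_id}.test.r{rep}", assay_id="cas9",
                         role=Role.CAS9_TRANSCRIPT, group=Group.TEST,
                         ct=baseline + cas9_dct, **common),
                CtRecord(f"{target_id}.test.r{rep}", assay_id="ubq",
                         role=Role.TRANSCRIPT_REFERENCE, group=Group.TEST,
                         ct=baseline, **common),
                CtRecord(f"{target_id}.ctrl.r{rep}", assay_id=target_id,
                         role=Role.TARGET_REGION, group=Group.CONTROL,
                         ct=baseline, **common),
                CtRecord(f"{target_id}.ctrl.r{rep}", assay_id="ubq",
                         role=Role.GENOMIC_REFERENCE, group=Group.CONTROL,
                         ct=baseline, **common),
            ]
    return records


@pytest.fixture
def worked_site_sequence() -> str:
    """23-nt sequence with a single forward NGG site (PAM at 20..22)."""
    return "ACGTACGTACGTACGTACGTTGG"
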