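import pytest

from ffascreen import (
    ActionHint,
    Impact,
    Panel,
    PanelCriterion,
    make_panel,
)


def _crit(cid, impact, og, domains=(), hint=None):
    default_hint = {
        Impact.POSITIVE: ActionHint.INSERTION,
        Impact.NEGATIVE: ActionHint.DELETION,
        Impact.REQUIRED: ActionHint.PRESENT_REQUIRED,
    }[impact]
    return PanelCriterion(
        criterion_id=cid,
        gene_symbol=f"g_{cid}",
        kegg_ko="K00001",
        ec_number="1.1.1.1",
        impact=impact,
        og_id=og,
        domain_accessions=tuple(domains),
        action_hint=hint or default_hint,
    )


@pytest.fixture
def small_panel():
    """3 criteria (one per impact class), hand-built: c1 positive with two
    domains, c2 negative with one, c3 required with none."""
    criteria = [
        _crit("c1", Impact.POSITIVE, "og1", ("D1", "D2")),
        _crit("c2", Impact.NEGATIVE, "og2", ("D3",)),
        _crit("c3", Impact.REQUIRED, "og3"),
    ]
    seqs = {"c1": "MKTAYIAKQR", "c2": "MSDNELWQHV", "c3": "MAGWLKFDTC"}
    return Panel.from_criteria(criteria, seqs)


@pytest.fixture
def backup_panel():
    """Required group with a primary enzyme and a backup co-member, plus one
    positive criterion."""
    criteria = [
        _crit("pos1", Impact.POSITIVE, "og_pos"),
        _crit("pps", Impact.REQUIRED, "og_pps"),
        _crit("pps_backup", Impact.REQUIRED, "og_pps"),
        _crit("req2", Impact.REQUIRED, "og_req2"),
    ]
    return Panel.from_criteria(criteria, {})


@pytest.fixture(scope="session")
def demo_panel():
    """Synthetic panel with the structure of the curated one: 64 criteria,
    12 required orthologous groups."""
    return make_panel(40, 12, 12, 12, 3, seed=5)
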