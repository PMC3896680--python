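"""Shared fixtures: domain sets, the packaged bank, and tiny hand-built tables."""

import pytest

import dcvkit as d


@pytest.fixture(scope="session")
def tdf14():
    return d.load_domain_set("tdf14")


@pytest.fixture(scope="session")
def bank():
    return d.packaged_item_bank()


@pytest.fixture()
def small_domains():
    return d.DomainSet(tuple(d.Domain(code=f"D{i}", label=f"dom{i}") for i in (1, 2, 3)))


@pytest.fixture()
def small_bank():
    return d.ItemBank(
        (
            d.ItemSpec(item_id="I1", intended_domains=("D1",),
                       text_by_language={"en": "Item one about [A]"}),
            d.ItemSpec(item_id="I2", intended_domains=("D2",),
                       text_by_language={"en": "Item two about [Ta]"}),
        )
    )


def make_table(rows, **kwargs):
    """rows: (judge, item, rank, domain, confidence) tuples."""
    return d.AllocationTable(
        [d.AllocationRecord(*r) for r in rows], **kwargs
    )


@pytest.fixture()
def worked_example_allocs():
    """The classic worked example: Knowledge at 60%, Skills at 20%."""
    return (
        d.AllocationRecord("J1", "I1", 1, "D1", 0.60),
        d.AllocationRecord("J1", "I1", 2, "D2", 0.20),
    )
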