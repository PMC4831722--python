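import pytest

from religator.fixtures import FixtureConfig, generate


@pytest.fixture(scope="session")
def small_fixture():
    """A small synthetic world shared by read-only tests."""
    return generate(FixtureConfig(seed=7, n_docs=20))


@pytest.fixture()
def pubtator_file(tmp_path):
    """A hand-written two-document PubTator file."""
    content = (
        "1001|t|Aspirin study\n"
        "1001|a|Aspirin induced asthma.\n"
        "1001\t0\t7\tAspirin\tChemical\tD001241\n"
        "1001\t14\t21\tAspirin\tChemical\tD001241\n"
        "1001\t30\t36\tasthma\tDisease\tD001249\n"
        "1001\tCID\tD001241\tD001249\n"
        "\n"
        "1002|t|Case report\n"
        "1002|a|Nausea after naproxen and ibuprofen dosing.\n"
        "1002\t12\t18\tNausea\tDisease\tD009325\n"
        "1002\t25\t33\tnaproxen\tChemical\tD009288\n"
        "1002\t38\t47\tibuprofen\tChemical\tD007052|D015257\n"
    )
    path = tmp_path / "corpus.pubtator"
    path.write_text(content, encoding="utf-8")
    return path
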