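import pytest

from alkfish.stats import ContingencyTable


@pytest.fixture(scope="session")
def pattern_contingency() -> ContingencyTable:
    """Concordance-group x pattern-set-size counts of the reference cohort."""
    return ContingencyTable(
        ((12, 14, 3), (137, 30, 1)),
        row_labels=("discordant", "concordant"),
        col_labels=("1", "2", "3"),
    )
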