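import pytest

from glycompose import default_ruleset, parse_name


@pytest.fixture
def rules():
    return default_ruleset()


@pytest.fixture
def rules_ds():
    return default_ruleset(double_sulfate=True)


@pytest.fixture
def fucoidan_fragment():
    """Disulfated deoxyhexose disaccharide, a fucoidan digest product."""
    return parse_name("DeoxyHex2 Sulfate2")
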