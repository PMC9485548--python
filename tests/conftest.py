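import pytest

from bodyfunc.lexicon import load_default_lexicons


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture(scope="session")
def allow(lexicons):
    from bodyfunc.lexicon import Category

    return lexicons[Category.SECTION_ALLOW]


@pytest.fixture(scope="session")
def filter_lex(lexicons):
    from bodyfunc.lexicon import Category

    return lexicons[Category.SECTION_FILTER]
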