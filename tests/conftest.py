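import pytest

from pascal import GeneratorConfig, LabeledSentence, RegimenVocabulary, generate_corpus


@pytest.fixture(scope="session")
def vocab() -> RegimenVocabulary:
    return RegimenVocabulary(("AC", "EC", "TH", "EC-TH", "AC-T", "FEC-P", "FEC-T", "EC-T", "TC", "TAC"))


@pytest.fixture(scope="session")
def small_vocab() -> RegimenVocabulary:
    return RegimenVocabulary(("AC", "EC-TH", "FEC-P"))


@pytest.fixture()
def toy_sentence(small_vocab) -> LabeledSentence:
    # "予EC 序贯 TH方案" with the 8-character mention labeled EC-TH
    chars = tuple("予EC序贯TH方案")
    tags = ("O", "B", "I", "I", "I", "I", "I", "O", "O")
    labels = ("O",) + ("EC-TH",) * 6 + ("O", "O")
    return LabeledSentence(chars, tags, labels, "s0", "p0")


@pytest.fixture(scope="session")
def tiny_corpora(vocab):
    """A small generated corpus shared by tests that need real data."""
    cfg = GeneratorConfig(regimens=vocab, counts=(120, 20, 40), n_patients=20, seed=11)
    return cfg, generate_corpus(cfg)
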