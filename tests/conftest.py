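import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from exsel.corpus import Conversation, Demonstration, Explanation, GoldExplanation, Utterance
from exsel.embeddings import HashEmbeddingBackend
from exsel.prompting import default_verbalizer
from exsel.ranking import read_criteria


@pytest.fixture(scope="session")
def backend():
    return HashEmbeddingBackend(seed=0)


@pytest.fixture(scope="session")
def verbalizer():
    return default_verbalizer()


@pytest.fixture(scope="session")
def criteria():
    from importlib import resources

    text = resources.files("exsel.data").joinpath("criteria_example.txt").read_text("utf-8")
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def make_conversation(texts_labels, conversation_id="conv0", speakers=None):
    utts = []
    for i, (text, label) in enumerate(texts_labels):
        speaker = speakers[i] if speakers else f"s{i % 2}"
        utts.append(
            Utterance(
                utterance_id=f"{conversation_id}_u{i}",
                speaker_id=speaker,
                text=text,
                position=i,
                gold_label=label,
            )
        )
    return Conversation(conversation_id=conversation_id, utterances=tuple(utts))


@pytest.fixture
def table2_conversation():
    """The four-utterance hospital dialogue used as the running example."""
    return make_conversation(
        [
            ("Where have you been?", "normal"),
            ("Oh! I wanted to hurt myself.", "depression"),
            ("What happened to you?", "normal"),
            ("I was broken, it's shocking.", "depression"),
        ]
    )


@pytest.fixture
def tiny_pool():
    demo = Demonstration(demo_id="d0", text="rainy commute and a broken umbrella", label="depression")
    gold = GoldExplanation(
        gold_id="g0",
        text="the post mentions a broken umbrella and sadness about the commute",
        demo_id="d0",
    )
    candidates = [
        Explanation(expl_id="e0", text="mentions broken umbrella and sadness about the commute", demo_id="d0"),
        Explanation(expl_id="e1", text="talks about commute weather and an umbrella", demo_id="d0"),
        Explanation(expl_id="e2", text="discusses gardening tips for spring tomatoes", demo_id="d0"),
    ]
    return demo, gold, candidates
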