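import itertools
from typing import List, Sequence

import pytest

from varlit.synth import CorpusSpec, fixture_catalog, generate_corpus
from varlit.types import MentionSpan


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(CorpusSpec(seed=11, n_docs=60))


def brute_force_max_matching(
    pred: Sequence[MentionSpan], gold: Sequence[MentionSpan], mode: str
) -> int:
    """Independent oracle: maximum one-to-one matching size by recursive
    enumeration over all assignments (feasible for <= 8 spans per side)."""

    def compatible(p: MentionSpan, g: MentionSpan) -> bool:
        if p.doc_id != g.doc_id:
            return False
        if mode == "exact":
            return p.start == g.start and p.end == g.end
        return p.start < g.end and g.start < p.end

    def best(i: int, used: frozenset) -> int:
        if i == len(pred):
            return 0
        score = best(i + 1, used)  # leave pred[i] unmatched
        for j, g in enumerate(gold):
            if j not in used and compatible(pred[i], g):
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())
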