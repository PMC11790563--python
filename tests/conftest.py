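import numpy as np
import pandas as pd
import pytest

from cultfit import RatingDataset, default_term_set

DEMO_DIC = """%
1\tpsychproc
2\tposemo\t1
3\tnegemo\t1
4\tfunct
5\tsocial
6\tarticle
%
happ*\t1 2
glad\t1 2
sad\t1 3
cry\t1 3
the\t4 6
a\t4 6
mate\t5
talk\t5
friend*\t5
"""


@pytest.fixture
def demo_dic_path(tmp_path):
    path = tmp_path / "demo.dic"
    path.write_text(DEMO_DIC, encoding="utf-8")
    return path


@pytest.fixture
def terms():
    return default_term_set()


def make_ratings_frame(n_participants=2, fill=3, terms=None):
    """Minimal well-formed ratings table: every rating = ``fill``."""
    terms = terms or default_term_set()
    rows = []
    for i in range(n_participants):
        culture = "heritage" if i % 2 == 0 else "host"
        for situation in ("pos_rel", "pos_auto", "neg_rel", "neg_auto"):
            row = {"participant_id": f"p{i}", "culture": culture,
                   "situation_type": situation}
            row.update({t: fill for t in terms.terms})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def small_dataset():
    return RatingDataset(table=make_ratings_frame(4))


def random_profiles(rng, n_per_culture=10, n_features=8,
                    situations=("pos_rel", "neg_rel")):
    """Random long profile table over two cultures (continuous features)."""
    rows = []
    for c, culture in enumerate(("heritage", "host")):
        for i in range(n_per_culture):
            for situation in situations:
                row = {"participant": f"{culture[:3]}{i}", "culture": culture,
                       "situation": situation}
                row.update({f"f{j}": rng.normal() for j in range(n_features)})
                rows.append(row)
    return pd.DataFrame(rows)
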