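import pytest

from mirmeta import Corpus, ListEntry, StudyRecord


def make_study(study_id, up=(), down=(), **kwargs):
    defaults = dict(year=2010, n_pairs=10, platform_size=400)
    defaults.update(kwargs)
    return StudyRecord(
        study_id=study_id,
        up_list=tuple(ListEntry(mirna=m) for m in up),
        down_list=tuple(ListEntry(mirna=m) for m in down),
        **defaults,
    )


@pytest.fixture
def tiny_corpus():
    """Three hand-built studies with overlapping up/down lists."""
    return Corpus(
        studies=(
            make_study("A", up=["miR-1", "miR-2", "miR-3", "miR-4"],
                       down=["miR-9", "miR-8"], n_pairs=8,
                       etiology_tags=frozenset({"HBV"})),
            make_study("B", up=["miR-1", "miR-5"],
                       down=["miR-8", "miR-7", "miR-9"], n_pairs=21,
                       etiology_tags=frozenset({"mixed"})),
            make_study("C", up=["miR-2", "miR-1"],
                       down=["miR-9"], n_pairs=30,
                       etiology_tags=frozenset({"HBV"})),
        )
    )
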