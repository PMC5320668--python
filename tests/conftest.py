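import numpy as np
import pytest

from epichain.model import BASE_CODE, ReadUnit, Segment


def seg(start: int, bases: str, eps: float = 0.01) -> Segment:
    codes = np.array([BASE_CODE[b] for b in bases], dtype=np.int8)
    return Segment(start, codes, np.full(len(bases), eps))


def read(rid: str, start: int, bases: str, eps: float = 0.01, *, mate=None) -> ReadUnit:
    segments = [seg(start, bases, eps)]
    if mate is not None:
        mstart, mbases = mate
        segments.append(seg(mstart, mbases, eps))
    return ReadUnit(id=rid, segments=segments)


@pytest.fixture
def tiny_window():
    from epichain.reference import ReferenceWindow

    return ReferenceWindow("chrT", 0, "AACGTTACGTAAGCATTGCATT")
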