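import numpy as np
import pytest

from svjoint.config import MatchConfig
from svjoint.fixtures import simulate_reference
from svjoint.sv_io import Reference, SVRecord, recompute_end


@pytest.fixture(scope="session")
def config() -> MatchConfig:
    return MatchConfig()


@pytest.fixture(scope="session")
def ref() -> Reference:
    reference, _ = simulate_reference(200_000, seed=7, chrom="1")
    return reference


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_ins(ref: Reference, chrom: str, pos: int, inserted: str,
             rid: str = "ins", source: str = "calls") -> SVRecord:
    anchor = ref.fetch(chrom, pos, pos)
    return SVRecord(
        chrom=chrom, pos=pos, end=pos, svtype="INS", length=len(inserted),
        ref_seq=anchor, alt_seq=anchor + inserted, record_id=rid, source=source,
    )


def make_del(ref: Reference, chrom: str, pos: int, length: int,
             rid: str = "del", source: str = "calls") -> SVRecord:
    return recompute_end(SVRecord(
        chrom=chrom, pos=pos, end=pos, svtype="DEL", length=length,
        ref_seq=ref.fetch(chrom, pos, pos + length),
        alt_seq=ref.fetch(chrom, pos, pos), record_id=rid, source=source,
    ))


def make_symbolic(chrom: str, pos: int, svtype: str, length: int,
                  rid: str = "sym", source: str = "calls") -> SVRecord:
    return recompute_end(SVRecord(
        chrom=chrom, pos=pos, end=pos, svtype=svtype, length=length,
        ref_seq="N", alt_seq="", symbolic=True, record_id=rid, source=source,
    ))
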