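import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synfun import AlignedSequenceSet, SequenceRecord, simulate_scenario
from synfun.io import AMINO_ACIDS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


RESIDUE_POOL = AMINO_ACIDS + "X"


def random_protein(rng: np.random.Generator, n: int, gap_frac: float = 0.0) -> str:
    chars = [RESIDUE_POOL[i] for i in rng.integers(0, len(RESIDUE_POOL), n)]
    if gap_frac > 0:
        gaps = rng.random(n) < gap_frac
        chars = ["-" if g else c for c, g in zip(chars, gaps)]
    return "".join(chars)


def make_record(residues: str, seq_id: str = "s1", species: str = "sp1",
                clade: str = "CL", paralog: str | None = None) -> SequenceRecord:
    return SequenceRecord(id=seq_id, species=species, clade=clade,
                          paralog=paralog, residues=residues)


def make_alignment(seqs: dict[str, str], **meta) -> AlignedSequenceSet:
    return AlignedSequenceSet(
        tuple(
            make_record(res, seq_id=sid, species=f"sp_{sid}", **meta)
            for sid, res in seqs.items()
        )
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The shipped synthetic scenario (fixed seed), generated once."""
    return simulate_scenario()
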