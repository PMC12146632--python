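import numpy as np
import pytest

from ighrecomb.config import Config
from ighrecomb.locus_model import ReferenceSet
from ighrecomb.read_profiler import EventClass, profile_sample
from ighrecomb.synthetic import (
    CloneMixSpec,
    CloneSpec,
    SimEventSpec,
    ToyLocusSpec,
    make_toy_locus,
    make_toy_sv_fixture,
    simulate_reads,
)


@pytest.fixture(scope="session")
def toy_locus():
    return make_toy_locus(ToyLocusSpec(seed=0))


@pytest.fixture(scope="session")
def sv_fixture():
    return make_toy_sv_fixture(seed=0)


@pytest.fixture
def config():
    return Config()


def all_class_clones():
    """One clone per simulatable event class, plus a germline clone."""
    events = [
        SimEventSpec(EventClass.complete_VDJ, ("IGHJ2", "IGHD3", "IGHV4")),
        SimEventSpec(EventClass.DJ_only, ("IGHJ1", "IGHD2")),
        SimEventSpec(EventClass.VD_only, ("IGHD3", "IGHV2")),
        SimEventSpec(EventClass.multiple_D, ("IGHJ2", "IGHD2", "IGHD4", "IGHV3")),
        SimEventSpec(EventClass.multiple_D, ("IGHD2", "IGHD3"), dd_as_deletion=True),
        SimEventSpec(EventClass.inversion_DJ, ("IGHJ3", "IGHD2")),
        SimEventSpec(EventClass.inversion_DD, ("IGHD2", "IGHD3")),
        SimEventSpec(EventClass.inversion_VD, ("IGHD3", "IGHV3")),
        None,
    ]
    n = len(events)
    return [CloneSpec(f"clone{i}", 1.0 / n, ev) for i, ev in enumerate(events)]


def profile_simulated(locus, sample, tmp_path, config=None, style="records"):
    """Write the truth SAM and run the full profiler over it."""
    sam = tmp_path / "truth.sam"
    sample.write_truth_sam(sam, style=style)
    refset = ReferenceSet([(locus.name, None, locus.locus_map)])
    kwargs = {} if config is None else {"config": config}
    return profile_sample({locus.name: str(sam)}, refset, **kwargs)


def simulate_all_classes(locus, depth=60, seed=11, error_rate=0.0):
    mix = CloneMixSpec(
        clones=all_class_clones(), depth=depth, error_rate=error_rate, seed=seed
    )
    return simulate_reads(locus, mix)
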