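import numpy as np
import pytest

from csvdnet.architecture import build_architecture
from csvdnet.core import LABEL_NAMES
from csvdnet.nn import Network
from csvdnet.phantom import PhantomConfig, cohort_patients, generate_patient_series, write_cohort
from csvdnet.preprocessing import build_stack_from_records, compute_dataset_stats, _ordered_qualifying


@pytest.fixture(scope="session")
def small_config():
    """A fast 3-patient cohort: 2 diseased, 1 control, mixed 64/256 matrices."""
    return PhantomConfig(
        n_diseased=2, n_control=1, slice_count_range=(8, 12),
        matrix_sizes=(64, 256), lesion_radius_vox=10.0, lesion_contrast=2.0,
        noise_sigma=0.02, seed=7,
    )


@pytest.fixture(scope="session")
def cohort_dir(small_config, tmp_path_factory):
    """The small cohort written to disk as DICOM series + manifest."""
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(small_config, out)
    return out


def micro_network(seed=0, l2=0.0, dropout=0.0):
    """A <1k-parameter model on a (6, 8, 8, 1) input for gradient checks."""
    spec = build_architecture(
        (6, 8, 8, 1), conv_filters=(2,), dense_units=(4,),
        dropout_rate=dropout, l2_coeff=l2,
    )
    return spec, Network.from_spec(spec, seed=seed)


def reduced_stacks(config, min_size=32, target=32, depth=24):
    """In-memory preprocessed stacks + labels + per-patient seeds."""
    roster = cohort_patients(config)
    series = {pid: generate_patient_series(config, pid, lab, s) for pid, lab, s in roster}
    stats = compute_dataset_stats(
        [s for pid in series for s in _ordered_qualifying(series[pid], min_size, target)]
    )
    stacks = {
        pid: build_stack_from_records(
            series[pid], stats, min_size=min_size, target=target, depth=depth,
            label=LABEL_NAMES[lab],
        )
        for pid, lab, _ in roster
    }
    return roster, stacks
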