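import numpy as np
import pytest

from glysite import io as gio
from glysite import synthetic as syn


@pytest.fixture(scope="session")
def signal_config():
    """Strong planted-signal study condition: enriched gapped dipeptides in
    glycosite flanks, exposure/coil shifts around glycosites, high
    within-class homology overlap."""
    return syn.GeneratorConfig(
        seed=20260923,
        n_glycoproteins=60,
        n_non_glycoproteins=60,
        planted_dipeptides=(
            ("W5N", 8.0), ("Y0N", 8.0), ("L2N", 8.0),
            ("N0Y", 8.0), ("N4W", 8.0), ("H6N", 8.0),
        ),
        sa_effect=0.4,
        ss_effect=0.35,
        overlap_boost=0.9,
    )


@pytest.fixture(scope="session")
def null_config():
    """Matched null condition: no enrichment, no SA/SS effect, no overlap boost."""
    return syn.GeneratorConfig(
        seed=20260923,
        n_glycoproteins=60,
        n_non_glycoproteins=60,
        sa_effect=0.0,
        ss_effect=0.0,
        overlap_boost=0.0,
    )


def make_labelled_windows(config, seed=None):
    """Annotated, labelled sequon windows + binary labels from a generator config."""
    if seed is not None:
        config = syn.replace(config, seed=seed)
    proteins, annotations = syn.generate_proteins(config)
    sa, ss = syn.generate_residue_annotations(proteins, annotations, config)
    windows = gio.build_dataset(proteins, annotations)
    annotated = gio.annotate_windows(windows, sa, ss)
    labelled = [a for a in annotated if a.window.label != gio.UNLABELED]
    y = np.array([1 if a.window.label == gio.POSITIVE else 0 for a in labelled])
    return proteins, labelled, y


@pytest.fixture(scope="session")
def signal_dataset(signal_config):
    return make_labelled_windows(signal_config)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    return make_labelled_windows(null_config)
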