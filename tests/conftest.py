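import numpy as np
import pytest

import targetfish as tf


def make_fingerprint(compound_id: str, features, radius: int = 2) -> tf.Fingerprint:
    """Hand-built sparse fingerprint for tests that control set overlap."""
    return tf.Fingerprint(compound_id=compound_id, features=frozenset(features), radius=radius)


def random_fingerprint(rng: np.random.Generator, compound_id: str, pool: int = 500,
                       size_lo: int = 5, size_hi: int = 60) -> tf.Fingerprint:
    size = int(rng.integers(size_lo, size_hi))
    feats = rng.choice(pool, size=size, replace=False)
    return make_fingerprint(compound_id, (int(f) for f in feats))


def planted_family_fps(rng, family_idx: int, n_members: int, base_size: int = 90,
                       unique_size: int = 10):
    """Fingerprints with within-family Tanimoto ~0.8 and zero between families.

    Members share ``base_size`` family-specific features and add
    ``unique_size`` private ones: pairwise t = 90/110 ~ 0.82.
    """
    offset = family_idx * 10_000
    base = set(range(offset, offset + base_size))
    fps = []
    for m in range(n_members):
        private = set(range(offset + 1000 + m * unique_size, offset + 1000 + (m + 1) * unique_size))
        fps.append(make_fingerprint(f"f{family_idx}m{m}", base | private))
    return fps


@pytest.fixture(scope="session")
def separable_library():
    """Planted 3 families x 2 scaffolds x 8 members, no inactive members."""
    cfg = tf.SynthConfig(n_families=3, scaffolds_per_family=2, members_per_scaffold=8,
                         inactive_fraction=0.0, seed=11)
    lib = tf.generate_library(cfg)
    fps = tf.compute_fingerprints(lib.molecules)
    return lib, fps


@pytest.fixture(scope="session")
def noisy_library():
    """Planted multi-scaffold families plus 30% inactive noise members."""
    cfg = tf.SynthConfig(n_families=3, scaffolds_per_family=2, members_per_scaffold=8,
                         inactive_fraction=0.3, seed=11)
    lib = tf.generate_library(cfg)
    fps = tf.compute_fingerprints(lib.molecules)
    return lib, fps


def record(atype="IC50", relation="=", value=1.0, unit="uM", compound="c1", family="F1",
           label=None):
    return tf.ActivityRecord(compound_id=compound, family_id=family, activity_type=atype,
                             relation=relation, value=value, unit=unit, explicit_label=label)
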