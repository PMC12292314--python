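import numpy as np
import pytest

import talofit as tf


@pytest.fixture(scope="session")
def reference_cohort() -> tf.CohortTable:
    return tf.load_reference_cohort()


@pytest.fixture(scope="session")
def reference_summary(reference_cohort) -> tf.CohortSummary:
    return tf.summarize_cohort(reference_cohort)


@pytest.fixture(scope="session")
def mean_case():
    """Synthetic joint whose gap field interpolates the reference means."""
    params = tf.SyntheticCaseParams(nodal_gaps=tf.REFERENCE_NODAL_MEANS.copy())
    tibia, talus, truth = tf.build_case_meshes(params)
    return params, tibia, talus, truth


@pytest.fixture(scope="session")
def mean_implant(reference_summary) -> tf.ImplantModel:
    """Standardized implant built from the reference cohort means."""
    return tf.build_implant_mesh(tf.ImplantSpec.from_summary(reference_summary))


@pytest.fixture()
def unit_square_mesh() -> tf.TriMesh:
    """Unit square at z=5 split into two triangles along the diagonal."""
    vertices = [(0, 0, 5.0), (1, 0, 5.0), (1, 1, 5.0), (0, 1, 5.0)]
    faces = [(0, 1, 2), (0, 2, 3)]
    return tf.TriMesh(np.array(vertices, float), np.array(faces), name="facet")
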