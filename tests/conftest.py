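import numpy as np
import pytest

from brainpath.catalog import (
    ParcellationLabels,
    PathwayInstance,
    aal116_labels,
    bundled_catalog_path,
    edges_from_sequence,
    expand_lateralization,
    load_catalog,
)
from brainpath.connectivity import ConnectivityMatrix


@pytest.fixture(scope="session")
def aal_labels() -> ParcellationLabels:
    return aal116_labels()


@pytest.fixture(scope="session")
def catalog_definitions(aal_labels):
    return load_catalog(bundled_catalog_path(), aal_labels)


@pytest.fixture(scope="session")
def catalog_instances(catalog_definitions):
    return expand_lateralization(catalog_definitions)


def make_connectivity(
    r: np.ndarray, labels: ParcellationLabels | None = None, subject_id: str = "s"
) -> ConnectivityMatrix:
    """Wrap a raw symmetric matrix as a ConnectivityMatrix with generated labels."""
    r = np.asarray(r, dtype=float)
    if labels is None:
        labels = ParcellationLabels(tuple(f"R{i:03d}" for i in range(r.shape[0])))
    return ConnectivityMatrix(subject_id=subject_id, r=r, labels=labels)


def chain_instance(region_names, closed: bool = False, pid: str = "toy") -> PathwayInstance:
    """Pathway instance from an explicit region sequence (no lateralization)."""
    return PathwayInstance(id=pid, edges=edges_from_sequence(tuple(region_names), closed))
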