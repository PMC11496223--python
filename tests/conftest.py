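import numpy as np
import pandas as pd
import pytest

from imgtx import (
    DonorExpression,
    ParcellationGeometry,
    make_sphere_parcellation,
)


@pytest.fixture(scope="session")
def sphere_geometry():
    """100-parcel synthetic sphere (50 per hemisphere)."""
    return make_sphere_parcellation(50, seed=0)


@pytest.fixture
def tiny_geometry():
    """Four hand-placed parcels, two per hemisphere, radius 10 mm."""
    xyz = 10.0 * np.array(
        [
            [-0.6, 0.8, 0.0],
            [-0.6, -0.8, 0.0],
            [0.6, 0.8, 0.0],
            [0.6, -0.8, 0.0],
        ]
    )
    return ParcellationGeometry(
        parcel_id=["L_1", "L_2", "R_1", "R_2"],
        hemisphere=np.array(["L", "L", "R", "R"], dtype=object),
        surface_xyz=xyz,
    )


def make_donor(
    donor_id: str,
    intensity: np.ndarray,
    probes: list[str],
    genes: list[str],
    xyz: np.ndarray | None = None,
    above: np.ndarray | None = None,
    rnaseq: pd.DataFrame | None = None,
) -> DonorExpression:
    n_samples = intensity.shape[0]
    sample_ids = [f"{donor_id}_s{i}" for i in range(n_samples)]
    if xyz is None:
        xyz = np.zeros((n_samples, 3))
    if above is None:
        above = np.ones_like(intensity, dtype=bool)
    return DonorExpression(
        donor_id=donor_id,
        sample_xyz=xyz,
        intensity=pd.DataFrame(intensity, index=sample_ids, columns=probes),
        above_background=pd.DataFrame(above, index=sample_ids, columns=probes),
        probe_gene=pd.Series(genes, index=probes),
        rnaseq_ref=rnaseq,
    )
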