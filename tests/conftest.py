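import pandas as pd
import pytest

from metroutes.examples import liver_crossseeding_patient, lymphatic_reseeding_patient
from metroutes.model import ClonalityMatrix, ClusterCCFMatrix, Lesion
from metroutes.pipeline import RouteAnalyzer


@pytest.fixture(scope="session")
def lymph_analysis():
    """Fitted pipeline for the lymph-node reseeding example patient."""
    return RouteAnalyzer().fit(lymphatic_reseeding_patient())


@pytest.fixture(scope="session")
def liver_analysis():
    """Fitted pipeline for the liver cross-seeding example patient."""
    return RouteAnalyzer().fit(liver_crossseeding_patient())


def make_matrix(ccf_rows, lesion_ids, n_mutations=None):
    """Build a ClusterCCFMatrix from {cluster: [ccf per lesion]}."""
    df = pd.DataFrame.from_dict(ccf_rows, orient="index", columns=lesion_ids)
    if n_mutations is None:
        n_mutations = {c: 10 for c in ccf_rows}
    return ClusterCCFMatrix(ccf=df, n_mutations=pd.Series(n_mutations))


def make_status(status_rows, lesion_ids):
    df = pd.DataFrame.from_dict(status_rows, orient="index", columns=lesion_ids)
    return ClonalityMatrix(status=df)


def lesions_for(layer_map):
    """Build single-region lesions from {lesion_id: layer}."""
    return [
        Lesion(lid, layer, (f"{lid}_s",)) for lid, layer in layer_map.items()
    ]
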