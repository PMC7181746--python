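"""Synthetic example patients illustrating the two canonical route patterns.

These are hand-constructed datasets (not measured data) whose clonality
structure reproduces the situations the method is built to resolve:

* :func:`lymphatic_reseeding_patient` — a colorectal primary with nine
  lymph-node metastases and one central node, where a subclone private to
  three paracolic nodes reveals that two of them were reseeded by the third
  rather than by the primary;
* :func:`liver_crossseeding_patient` — a primary with three liver
  metastases, two of which share a private clonal subclone and identical
  composition, so one must have seeded the other but the direction is
  conventional (an ambiguity group).

Each helper returns a full per-region mutation table (uniform 264X depth;
the primary has two regions whose CCFs straddle the lesion value so the
depth-weighted merge is exercised end to end).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import Lesion, MutationCall, PatientDataset

__all__ = ["lymphatic_reseeding_patient", "liver_crossseeding_patient"]

_DEPTH = 264


def _build_dataset(
    patient_id: str,
    lesions: List[Lesion],
    cluster_ccf: Dict[str, Dict[str, float]],  # cluster -> lesion -> mean CCF
    n_mutations: Dict[str, int],
    straddle: float = 0.05,
) -> PatientDataset:
    """Expand lesion-level cluster CCFs into a per-region mutation table.

    Single-region lesions carry the value verbatim; two-region lesions get
    value +/- ``straddle`` (clipped to [0, 1]) in their two regions so the
    equal-depth merge recovers the value exactly.
    """
    records = []
    idx = 0
    for cluster, per_lesion in cluster_ccf.items():
        for i in range(n_mutations[cluster]):
            idx += 1
            mid = f"m{idx:04d}"
            for lesion in lesions:
                value = per_lesion[lesion.lesion_id]
                n_regions = len(lesion.region_sample_ids)
                for r, sid in enumerate(lesion.region_sample_ids):
                    if n_regions == 2 and 0.0 < value < 1.0:
                        delta = min(straddle, value, 1.0 - value)
                        ccf = value + delta if r == 0 else value - delta
                    else:
                        ccf = value
                    records.append(
                        MutationCall(
                            mutation_id=mid,
                            sample_id=sid,
                            ccf=ccf,
                            depth=_DEPTH,
                            cluster_id=cluster,
                        )
                    )
    return PatientDataset(patient_id=patient_id, lesions=lesions, mutations=records)


def lymphatic_reseeding_patient() -> PatientDataset:
    """Synthetic patient with paracolic-to-paracolic reseeding.

    Seven mutation clusters on the tree 1-2-3 with 3-{4,5,6} and 2-7.
    Cluster 1 is the trunk; cluster 2 is present everywhere but subclonal
    in the primary, so it is a branch, not a second trunk. Cluster 7 is
    private to P6/P7/P8: P7 and P8 can only have been seeded by P6, while
    P6's remaining clones trace back to the primary. I1 and I2 are
    monoclonal (all present clusters clonal); the other eight metastases
    are multiclonal.
    """
    lesions = [
        Lesion("T", "T", ("T_R1", "T_R2")),
        Lesion("P1", "P", ("P1_s",)),
        Lesion("P2", "P", ("P2_s",)),
        Lesion("P5", "P", ("P5_s",)),
        Lesion("P6", "P", ("P6_s",)),
        Lesion("P7", "P", ("P7_s",)),
        Lesion("P8", "P", ("P8_s",)),
        Lesion("P9", "P", ("P9_s",)),
        Lesion("I1", "I", ("I1_s",)),
        Lesion("I2", "I", ("I2_s",)),
        Lesion("C1", "C", ("C1_s",)),
    ]
    #           T     P1    P2    P5    P6    P7    P8    P9    I1    I2    C1
    table = {
        "1": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
        "2": (0.80, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95),
        "3": (0.60, 0.40, 0.60, 0.65, 0.50, 0.00, 0.30, 0.50, 0.92, 0.00, 0.40),
        "4": (0.20, 0.00, 0.20, 0.30, 0.20, 0.00, 0.00, 0.00, 0.90, 0.00, 0.00),
        "5": (0.20, 0.00, 0.30, 0.20, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00),
        "6": (0.10, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.25, 0.00, 0.00, 0.00),
        "7": (0.00, 0.00, 0.00, 0.00, 0.25, 0.40, 0.40, 0.00, 0.00, 0.00, 0.00),
    }
    lesion_ids = [l.lesion_id for l in lesions]
    cluster_ccf = {
        c: dict(zip(lesion_ids, vals)) for c, vals in table.items()
    }
    n_mutations = {"1": 40, "2": 18, "3": 15, "4": 12, "5": 10, "6": 8, "7": 7}
    return _build_dataset("EX_LYMPH", lesions, cluster_ccf, n_mutations)


def liver_crossseeding_patient() -> PatientDataset:
    """Synthetic patient with liver-to-liver reseeding.

    Four clusters on the tree 1-2-3 and 1-4. LM3 shares the private branch
    cluster 4 with the primary only, so it was seeded directly. LM1 and LM2
    share cluster 3, clonal in both and absent everywhere else, with
    otherwise identical composition: one seeded the other, direction
    conventional. All three liver metastases are monoclonal.
    """
    lesions = [
        Lesion("T", "T", ("T_R1", "T_R2")),
        Lesion("LM1", "LM", ("LM1_R1", "LM1_R2")),
        Lesion("LM2", "LM", ("LM2_R1", "LM2_R2")),
        Lesion("LM3", "LM", ("LM3_R1", "LM3_R2")),
    ]
    #           T     LM1   LM2   LM3
    table = {
        "1": (1.00, 1.00, 1.00, 1.00),
        "2": (0.40, 1.00, 1.00, 0.00),
        "3": (0.00, 0.95, 0.95, 0.00),
        "4": (0.30, 0.00, 0.00, 0.95),
    }
    lesion_ids = [l.lesion_id for l in lesions]
    cluster_ccf = {c: dict(zip(lesion_ids, vals)) for c, vals in table.items()}
    n_mutations = {"1": 35, "2": 12, "3": 9, "4": 10}
    return _build_dataset("EX_LIVER", lesions, cluster_ccf, n_mutations)
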