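"""Composition of the public benchmark valve-image collections.

Per-taxon valve counts of the three published brightfield collections the
method was designed around: the mixed AQUALITAS/DIADIST life-cycle set
(eight taxa), the Sellaphora species complex (six taxa) and the Gomphonema
set (five taxa).  Only the printed counts are carried here — the images
themselves are not redistributable and are emulated by
:mod:`diatomid.synthetic`.
"""

from __future__ import annotations

AQUALITAS_DIADIST_COUNTS: dict[str, int] = {
    "Gomphonema minutum": 74,
    "Luticola goeppertiana": 117,
    "Nitzschia amphibia": 59,
    "Nitzschia capitellata": 95,
    "Eunotia tenella": 68,
    "Fragilariforma bicapitata": 100,
    "Gomphonema augur var augur": 98,
    "Stauroneis smithii grunow": 92,
}

SELLAPHORA_COUNTS: dict[str, int] = {
    "Sellaphora pupula": 40,
    "Sellaphora obesa": 72,
    "Sellaphora blackfordensis": 57,
    "Sellaphora capitata": 120,
    "Sellaphora auldreekie": 40,
    "Sellaphora lanceolata": 53,
}

GOMPHONEMA_COUNTS: dict[str, int] = {
    "Gomphonema acidoclinatum": 76,
    "Gomphonema auritum": 40,
    "Gomphonema gracile": 28,
    "Gomphonema jadwigiae": 72,
    "Gomphonema parvulum var parvulum": 28,
}


def dataset_totals() -> dict[str, int]:
    """Total valve counts of the three reference collections."""
    return {
        "aqualitas_diadist": sum(AQUALITAS_DIADIST_COUNTS.values()),
        "sellaphora": sum(SELLAPHORA_COUNTS.values()),
        "gomphonema": sum(GOMPHONEMA_COUNTS.values()),
    }
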