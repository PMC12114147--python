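"""Bundled reference tables.

Two small fixtures ship with the package:

* ``metabolite_annotations`` — the 36-row annotation table of strawberry
  fruit/leaf metabolites from untargeted negative-mode LC-MS/MS
  (tentative identity, class, MW, [M-H]- m/z, fragment ions, retention
  time, tissue presence), transcribed from the published table verbatim;
  the printed numbering runs to 37 but skips one row, and the printed
  presence flags give 11 shared metabolites where the running text says
  10 — the transcription preserves the table as printed.
* ``query_compounds`` — the 24 structurally characterised metabolites
  submitted to the NOX2 activity screen, with their printed SMILES
  (kept verbatim, including two entries whose SMILES do not match their
  names chemically) and the published consensus call for reference.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_io import CompoundRecord, MetaboliteRecord, load_metabolite_table


def _data_path(filename: str):
    return resources.files("phytonox.data") / filename


def metabolite_annotations() -> list[MetaboliteRecord]:
    """The bundled fruit/leaf metabolite annotation table as records."""
    with resources.as_file(_data_path("metabolite_annotations.csv")) as path:
        return load_metabolite_table(path)


def query_compound_table() -> pd.DataFrame:
    """Raw query-compound table (id, formula, smiles, reported consensus)."""
    with resources.as_file(_data_path("query_compounds.csv")) as path:
        return pd.read_csv(path)


def query_compounds() -> list[CompoundRecord]:
    """The 24 query compounds as unlabeled records, input order preserved."""
    frame = query_compound_table()
    return [
        CompoundRecord(id=str(row.id), smiles=str(row.smiles))
        for row in frame.itertuples(index=False)
    ]
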