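"""Bundled curated tables: the published 46,XY DSD cohort fixtures.

Two small tab-separated tables ship with the package: the 32-patient
cohort description and the 27-row table of VUS in the 15 candidate genes
identified in that cohort.  They serve as worked-example inputs and as
ground truth for the package's own tests.
"""

from __future__ import annotations

from importlib.resources import files

from .tables_io import PatientRecord, VariantRecord, read_patient_table, read_variant_table

__all__ = ["load_cohort_variants", "load_cohort_patients"]


def _data_path(name: str):
    return files("crossprio.data").joinpath(name)


def load_cohort_variants() -> list[VariantRecord]:
    """The 27 candidate-gene VUS observed across the 32-patient cohort."""
    with _data_path("dsd_vus_table.tsv").open("rb") as fh:
        return read_variant_table(fh, dialect="tsv")


def load_cohort_patients() -> list[PatientRecord]:
    """The 32-patient 46,XY cohort with uninformative exomes."""
    with _data_path("dsd_patient_table.tsv").open("rb") as fh:
        return read_patient_table(fh)
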