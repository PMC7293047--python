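"""Bundled data: class tables, CANA mapping, published count fixtures.

``ntc_classes_synthetic.csv`` carries the real 96-class / 14-code
structure of the conformer alphabet (class names, per-code memberships)
but synthetic geometry columns — deterministic family-anchored stand-ins,
since the reference geometries live in an external database.  The two
count tables are published incidence counts: conformer classes inside
vs outside riboswitch ligand-binding sites, and in ribosome X-ray vs
cryo-EM structures.
"""

from importlib import resources
from pathlib import Path

from ..cana import CanaMapping, load_mapping
from ..classify import ClassTable, load_class_table
from ..stats import ContingencyTable, load_counts_csv

__all__ = [
    "data_path",
    "bundled_class_table",
    "bundled_cana_mapping",
    "riboswitch_counts",
    "ribosome_counts",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    path = resources.files(__package__) / name
    return Path(str(path))


def bundled_class_table() -> ClassTable:
    """The 96-class table (synthetic geometry, real name/code structure)."""
    return load_class_table(data_path("ntc_classes_synthetic.csv"))


def bundled_cana_mapping() -> CanaMapping:
    """The full NtC -> CANA mapping, including NANT -> NAN."""
    return load_mapping(data_path("cana_mapping.csv"))


def riboswitch_counts() -> ContingencyTable:
    """Conformer counts inside/outside riboswitch binding sites."""
    return load_counts_csv(data_path("riboswitch_site_counts.csv"))


def ribosome_counts() -> ContingencyTable:
    """Conformer counts in ribosome X-ray vs cryo-EM structures."""
    return load_counts_csv(data_path("ribosome_method_counts.csv"))
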