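"""Packaged worked-example tables.

Three small colorectal/ovarian-cancer tables ship with the package so the
whole pipeline can be exercised without any external dataset:

``table1``
    5 patients × (5 conditional attributes + survival-period decision).
    Note: the source table's first two column headers (sex/age) do not match
    the printed values; the fixture stores the six columns exactly as the
    table renders, with ``a1`` holding the 45/35/65/36/64 column.
``table3``
    The same 5 patients after feature reduction, with a 0/1 event column.
``table11``
    20 patients × 23 conditional attributes (6 clinical + 17 microarray
    probes), Dukes stage decision ``d`` (0–3) and event indicator.
"""

from __future__ import annotations

from importlib import resources

from .infosys import InformationSystem, load_information_system

__all__ = ["fixture", "FIXTURE_NAMES"]

_SCHEMAS = {
    "table1": {"decision": "d"},
    "table3": {"event": "event"},
    "table11": {
        "decision": "d",
        "time": "DFS",
        "event": "event",
        "categorical": ["Gender", "LOC", "AdjRadio", "AdjChem"],
    },
}

FIXTURE_NAMES = tuple(sorted(_SCHEMAS))


def fixture(name: str) -> InformationSystem:
    """Return one of the packaged tables as an :class:`InformationSystem`.

    Raises
    ------
    KeyError
        If ``name`` is not one of ``table1``, ``table3``, ``table11``.
    """
    if name not in _SCHEMAS:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    with resources.as_file(
        resources.files("roughstage.data").joinpath(f"{name}.csv")
    ) as path:
        return load_information_system(path, _SCHEMAS[name])
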