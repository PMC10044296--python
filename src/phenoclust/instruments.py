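"""Item registry for the three symptom questionnaires.

The analysis pools 43 self-report items: the 20-item CES-D depression
scale, the 7-item anxiety subscale of the HADS, and the 16-item subset of
the PSQI sleep-quality questionnaire that enters clustering (the full
24-item PSQI layout is configurable).  Items are identified by short keys
(``"CESD_03"``) and carried through the pipeline in a fixed canonical
order -- CES-D 1-20, HADS-A 1-7, then PSQI -- so that column indexing is
reproducible across runs and samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import RegistryError

INSTRUMENTS = ("CESD", "HADS_A", "PSQI")

# Radloff's four CES-D subscales, used only as descriptive metadata.
_CESD_SUBSCALES = {
    3: "depressed affect", 6: "depressed affect", 9: "depressed affect",
    10: "depressed affect", 14: "depressed affect", 17: "depressed affect",
    18: "depressed affect",
    4: "positive affect", 8: "positive affect", 12: "positive affect",
    16: "positive affect",
    15: "interpersonal", 19: "interpersonal",
    1: "somatic", 2: "somatic", 5: "somatic", 7: "somatic",
    11: "somatic", 13: "somatic", 20: "somatic",
}

_CESD_LABELS = {
    1: "bothered by things", 2: "poor appetite", 3: "could not shake blues",
    4: "felt as good as others", 5: "trouble keeping mind on task",
    6: "felt depressed", 7: "everything an effort", 8: "hopeful about future",
    9: "life a failure", 10: "felt fearful", 11: "restless sleep",
    12: "was happy", 13: "talked less than usual", 14: "felt lonely",
    15: "people were unfriendly", 16: "enjoyed life", 17: "crying spells",
    18: "felt sad", 19: "felt disliked", 20: "could not get going",
}

_HADS_A_LABELS = {
    1: "tense or wound up", 2: "frightened feeling of dread",
    3: "worrying thoughts", 4: "can sit at ease and feel relaxed",
    5: "butterflies in the stomach", 6: "restless, has to be on the move",
    7: "sudden feelings of panic",
}


@dataclass(frozen=True)
class ItemDescriptor:
    """One questionnaire item.

    ``item_id`` is the unique key used as a column name throughout;
    ``instrument`` is one of :data:`INSTRUMENTS`; ``subscale`` is optional
    descriptive metadata.
    """

    item_id: str
    instrument: str
    label: str = ""
    subscale: str | None = None

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise RegistryError(
                f"unknown instrument {self.instrument!r} for item {self.item_id!r}; "
                f"expected one of {INSTRUMENTS}"
            )


def default_instrument_config(n_psqi: int = 16) -> dict[str, list[dict]]:
    """Default instrument spec: 20 CES-D + 7 HADS-A + ``n_psqi`` PSQI items.

    The 16-item PSQI default matches the set of sleep items that enters
    clustering; pass ``n_psqi=24`` for the full questionnaire layout.
    """
    cfg: dict[str, list[dict]] = {"CESD": [], "HADS_A": [], "PSQI": []}
    for i in range(1, 21):
        cfg["CESD"].append(
            {"item_id": f"CESD_{i:02d}", "label": _CESD_LABELS[i],
             "subscale": _CESD_SUBSCALES[i]}
        )
    for i in range(1, 8):
        cfg["HADS_A"].append(
            {"item_id": f"HADSA_{i:02d}", "label": _HADS_A_LABELS[i]}
        )
    for i in range(1, n_psqi + 1):
        cfg["PSQI"].append(
            {"item_id": f"PSQI_{i:02d}", "label": f"sleep complaint {i}"}
        )
    return cfg


def build_registry(
    config: Mapping[str, Sequence] | None = None,
) -> list[ItemDescriptor]:
    """Build the ordered item registry from an instrument spec.

    ``config`` maps instrument names to item lists; each entry is either a
    bare item-id string or a mapping with ``item_id`` and optional
    ``label``/``subscale`` keys.  Instruments are emitted in canonical
    order (CESD, HADS_A, PSQI); items keep their listed order.  With no
    config the default 43-item registry is returned.
    """
    if config is None:
        config = default_instrument_config()
    unknown = set(config) - set(INSTRUMENTS)
    if unknown:
        raise RegistryError(
            f"unknown instrument(s) {sorted(unknown)}; expected subset of {INSTRUMENTS}"
        )
    registry: list[ItemDescriptor] = []
    seen: set[str] = set()
    for instrument in INSTRUMENTS:
        for entry in config.get(instrument, ()):
            if isinstance(entry, str):
                entry = {"item_id": entry}
            desc = ItemDescriptor(
                item_id=str(entry["item_id"]),
                instrument=instrument,
                label=str(entry.get("label", "")),
                subscale=entry.get("subscale"),
            )
            if desc.item_id in seen:
                raise RegistryError(f"duplicate item_id {desc.item_id!r} in registry")
            seen.add(desc.item_id)
            registry.append(desc)
    if not registry:
        raise RegistryError("empty registry: config lists no items")
    return registry


def registry_from_yaml(path) -> list[ItemDescriptor]:
    """Load an instrument spec from a YAML (or JSON) file and build the registry."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise RegistryError(f"instrument spec in {path} must be a mapping")
    return build_registry(config)


def item_ids(registry: Iterable[ItemDescriptor]) -> list[str]:
    return [d.item_id for d in registry]
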