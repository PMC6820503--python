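"""Human-editable study configuration files: designs, panels and gates.

Designs and panels travel as CSV (one row per donor-sample / marker), gate
trees as YAML. All of these are plain text so a study is fully described
by files a reviewer can read and edit.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from ..containers import PanelDefinition, StudyDesign, PREGNANT, POSTPARTUM
from ..errors import ConfigError, FormatError
from ..gating import GateDefinition, GateTree


# -- study design --------------------------------------------------------

def read_design(path) -> StudyDesign:
    """Read a design CSV: columns donor, group, cohort, optional paired_with.

    ``paired_with`` on a pregnant row names that woman's postpartum
    donor-sample id (or vice versa); the pairing must resolve to existing
    donors of the stated groups.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"donor", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"design file {path} must have columns {sorted(required)}")
    if "cohort" not in df.columns:
        df["cohort"] = "discovery"
    donors = df.set_index("donor")[["group", "cohort"]]
    pairing: dict[str, str] = {}
    if "paired_with" in df.columns:
        for _, row in df.iterrows():
            partner = row["paired_with"]
            if not partner:
                continue
            if partner not in donors.index:
                raise ConfigError(
                    f"donor {row['donor']!r} paired with nonexistent donor {partner!r}"
                )
            if row["group"] == PREGNANT:
                pairing[row["donor"]] = partner
            elif row["group"] == POSTPARTUM:
                pairing[partner] = row["donor"]
            else:
                raise ConfigError(
                    f"pairing declared on donor {row['donor']!r} of group {row['group']!r}"
                )
    return StudyDesign(donors=donors, pairing=pairing)


def write_design(design: StudyDesign, path) -> None:
    df = design.donors.reset_index(names="donor").copy()
    inverse = {v: k for k, v in design.pairing.items()}
    df["paired_with"] = [
        design.pairing.get(d, inverse.get(d, "")) for d in df["donor"]
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# -- panel ---------------------------------------------------------------

def read_panel(path) -> PanelDefinition:
    """Read a panel CSV: columns marker, tag, category."""
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("marker", "tag", "category"):
        if col not in df.columns:
            raise FormatError(f"panel file {path} must have a {col!r} column")
    return PanelDefinition(entries=[tuple(r) for r in df[["marker", "tag", "category"]].itertuples(index=False)])


def write_panel(panel: PanelDefinition, path) -> None:
    pd.DataFrame(panel.entries, columns=["marker", "tag", "category"]).to_csv(path, index=False)


# -- gates ---------------------------------------------------------------

def _gate_from_mapping(d: dict) -> GateDefinition:
    try:
        return GateDefinition(
            marker=str(d["marker"]), threshold=float(d["threshold"]), polarity=str(d["polarity"])
        )
    except KeyError as exc:
        raise FormatError(f"gate entry missing key {exc.args[0]!r}: {d}") from None


def read_gates(path) -> GateTree:
    """Read a gate-tree YAML file.

    Layout::

        scale: arcsinh
        root_name: NK
        gates:                       # root conjunction
          - {marker: CD3, threshold: 1.5, polarity: below}
          ...
        populations:                 # optional terminal populations
          NK_dim:
            - {marker: CD56, threshold: 1.2, polarity: above}
            ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "gates" not in doc:
        raise FormatError(f"gate file {path} must be a mapping with a 'gates' list")
    gates = [_gate_from_mapping(g) for g in doc["gates"]]
    populations = {
        str(name): [_gate_from_mapping(g) for g in defs]
        for name, defs in (doc.get("populations") or {}).items()
    }
    return GateTree(
        gates=gates,
        populations=populations,
        root_name=str(doc.get("root_name", "root")),
        scale=str(doc.get("scale", "arcsinh")),
    )


def write_gates(tree: GateTree, path) -> None:
    doc = {
        "scale": tree.scale,
        "root_name": tree.root_name,
        "gates": [
            {"marker": g.marker, "threshold": float(g.threshold), "polarity": g.polarity}
            for g in tree.gates
        ],
    }
    if tree.populations:
        doc["populations"] = {
            name: [
                {"marker": g.marker, "threshold": float(g.threshold), "polarity": g.polarity}
                for g in defs
            ]
            for name, defs in tree.populations.items()
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def link_tables_to_design(tables_by_donor, design: StudyDesign) -> None:
    """Check that every donor with cells appears in the design."""
    design.check_donors_known(tables_by_donor.keys())
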