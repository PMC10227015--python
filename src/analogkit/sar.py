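"""Structure-activity-relationship ledger and campaign arithmetic.

Per-compound experimental summaries (thermal shift, dissociation constant,
enzymatic and cellular IC50, kinase-selectivity ratio) with parent links
forming the optimization decision tree.  The ledger performs the campaign's
derived arithmetic - fold-changes, shift differences - and exports the
decision tree with per-node annotations.  Censored values (stored with a
"<" or ">" comparator) never enter ratios.
"""

from __future__ import annotations

import csv
import importlib.resources
import io as _io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .errors import CensoredValueError, LedgerIntegrityError

FIELDS = ("delta_tm", "kd", "enzymatic_ic50", "cellular_ic50",
          "selectivity_ratio_il3_scf")

_CSV_COLUMNS = ("id", "parent", "field", "value", "comparator", "units",
                "provenance")


@dataclass(frozen=True)
class SarValue:
    value: float
    comparator: str = "="  # "=", "<", ">"
    units: str = ""
    provenance: str = ""

    @property
    def censored(self) -> bool:
        return self.comparator in ("<", ">")


@dataclass
class SarRecord:
    compound_id: str
    parent: Optional[str] = None
    values: Dict[str, SarValue] = field(default_factory=dict)

    def get(self, fieldname: str) -> Optional[SarValue]:
        return self.values.get(fieldname)


class SarLedger:
    """Records keyed by compound id; parent edges must form a forest."""

    def __init__(self):
        self.records: Dict[str, SarRecord] = {}

    # -- construction -------------------------------------------------------

    def add(self, compound_id: str, parent: Optional[str] = None,
            **values) -> SarRecord:
        rec = self.records.setdefault(compound_id,
                                      SarRecord(compound_id, parent))
        if parent is not None:
            rec.parent = parent
        for fname, v in values.items():
            if fname not in FIELDS:
                raise LedgerIntegrityError(f"unknown SAR field {fname!r}")
            rec.values[fname] = v if isinstance(v, SarValue) else SarValue(float(v))
        return rec

    @classmethod
    def from_csv(cls, source) -> "SarLedger":
        """Load the long-format ledger CSV (id,parent,field,value,...)."""
        ledger = cls()
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        reader = csv.DictReader(_io.StringIO(text))
        for row in reader:
            cid = row["id"].strip()
            parent = row.get("parent", "").strip() or None
            fname = row["field"].strip()
            if fname not in FIELDS:
                raise LedgerIntegrityError(f"unknown SAR field {fname!r}")
            val = SarValue(value=float(row["value"]),
                           comparator=row.get("comparator", "=").strip() or "=",
                           units=row.get("units", "").strip(),
                           provenance=row.get("provenance", "").strip())
            rec = ledger.records.setdefault(cid, SarRecord(cid, parent))
            if parent is not None:
                rec.parent = parent
            rec.values[fname] = val
        ledger.validate()
        return ledger

    def to_csv(self) -> str:
        buf = _io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(_CSV_COLUMNS)
        for cid in self.records:
            rec = self.records[cid]
            for fname, v in rec.values.items():
                w.writerow([cid, rec.parent or "", fname, f"{v.value:g}",
                            v.comparator, v.units, v.provenance])
        return buf.getvalue()

    # -- integrity ----------------------------------------------------------

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.records)
        for cid, rec in self.records.items():
            if rec.parent is not None:
                if rec.parent == cid:
                    raise LedgerIntegrityError(f"{cid} is its own parent")
                if rec.parent not in self.records:
                    raise LedgerIntegrityError(
                        f"{cid} refers to unknown parent {rec.parent!r}")
                g.add_edge(rec.parent, cid)
        return g

    def validate(self) -> None:
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            raise LedgerIntegrityError("decision-tree edges contain a cycle")

    # -- arithmetic ---------------------------------------------------------

    def _value(self, compound_id: str, fieldname: str) -> SarValue:
        if compound_id not in self.records:
            raise KeyError(f"unknown compound {compound_id!r}")
        v = self.records[compound_id].get(fieldname)
        if v is None:
            raise KeyError(f"{compound_id} has no value for {fieldname!r}")
        return v

    def fold_change(self, numerator_id: str, denominator_id: str,
                    fieldname: str) -> float:
        """value(numerator) / value(denominator); censored operands refuse."""
        num = self._value(numerator_id, fieldname)
        den = self._value(denominator_id, fieldname)
        for cid, v in ((numerator_id, num), (denominator_id, den)):
            if v.censored:
                raise CensoredValueError(
                    f"{cid}.{fieldname} is censored ({v.comparator} {v.value:g})")
        return num.value / den.value

    def delta_field(self, id_a: str, id_b: str, fieldname: str) -> float:
        """value(a) - value(b), signed."""
        return (self._value(id_a, fieldname).value
                - self._value(id_b, fieldname).value)

    # -- decision tree ------------------------------------------------------

    def decision_tree_export(self) -> dict:
        """Topologically ordered nodes annotated with dTm and cellular IC50.

        Each node reports its headline values and, when the parent also has
        the value, whether the child improved (dTm: higher is better;
        IC50: lower is better).
        """
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            raise LedgerIntegrityError("decision-tree edges contain a cycle")
        order = list(nx.lexicographical_topological_sort(g))
        nodes = []
        for cid in order:
            rec = self.records[cid]
            dtm = rec.get("delta_tm")
            ic50 = rec.get("cellular_ic50")
            node = {
                "id": cid,
                "parent": rec.parent,
                "delta_tm": dtm.value if dtm else None,
                "cellular_ic50": ic50.value if ic50 else None,
            }
            if rec.parent:
                prec = self.records[rec.parent]
                p_dtm, p_ic = prec.get("delta_tm"), prec.get("cellular_ic50")
                node["delta_tm_improved"] = (
                    dtm.value > p_dtm.value if dtm and p_dtm else None)
                node["cellular_ic50_improved"] = (
                    ic50.value < p_ic.value if ic50 and p_ic else None)
            nodes.append(node)
        edges = [(rec.parent, cid) for cid, rec in self.records.items()
                 if rec.parent]
        return {"nodes": nodes, "edges": sorted(edges)}

    def to_dot(self) -> str:
        """GraphViz DOT text of the decision tree with headline annotations."""
        tree = self.decision_tree_export()
        lines = ["digraph sar {", "  rankdir=TB;"]
        for node in tree["nodes"]:
            parts = [node["id"]]
            if node["delta_tm"] is not None:
                parts.append(f"dTm {node['delta_tm']:g} C")
            if node["cellular_ic50"] is not None:
                parts.append(f"IC50 {node['cellular_ic50']:g} nM")
            label = "\\n".join(parts)
            lines.append(f'  "{node["id"]}" [label="{label}"];')
        for parent, child in tree["edges"]:
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        return "\n".join(lines)


def maintext_ledger() -> SarLedger:
    """The shipped fixture ledger holding only main-text campaign values."""
    text = importlib.resources.files("analogkit.data").joinpath(
        "sar_maintext.csv").read_text()
    return SarLedger.from_csv(_io.StringIO(text))
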