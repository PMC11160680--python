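"""Model file reading/writing and minimal diagram export.

Two model formats are supported:

* JSON: ``{"states": [...], "edges": [{"from": i, "to": j, "rate": name,
  "value": number|null, "process": ..., "ligand": ..., "side": ...,
  "order": 1|2, "concentration": ...}, ...]}``
* CSV rate matrix: header row and column of state labels; empty or 0
  cells mean "no edge".
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

from .graph_core import (
    DiagramError,
    DirectionalDiagram,
    FluxDiagram,
    KineticDiagram,
    PartialDiagram,
    load_diagram,
    rate_name,
)

__all__ = ["read_model", "write_model", "export_diagrams"]


def read_model(path: str | Path) -> tuple[KineticDiagram, dict[str, float]]:
    """Load a kinetic model file; returns (diagram, numeric rate values).

    The value map only contains entries for edges that declared a numeric
    value (JSON) or for every edge (CSV matrix).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        return _read_csv_matrix(path)
    raise DiagramError(f"unrecognized model file type: {path.suffix!r}")


def _read_json(path: Path) -> tuple[KineticDiagram, dict[str, float]]:
    doc = json.loads(path.read_text())
    try:
        edges = doc["edges"]
    except (TypeError, KeyError):
        raise DiagramError("JSON model must contain an 'edges' list") from None
    diagram = load_diagram(edges, states=doc.get("states"))
    values = {}
    for rec in edges:
        if rec.get("value") is not None:
            values[rate_name(int(rec["from"]), int(rec["to"]))] = float(rec["value"])
    return diagram, values


def _read_csv_matrix(path: Path) -> tuple[KineticDiagram, dict[str, float]]:
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if r]
    header = [int(x) for x in rows[0][1:]]
    n = len(header)
    values: dict[str, float] = {}
    matrix = [[0.0] * n for _ in range(n)]
    for row in rows[1:]:
        i = int(row[0])
        for col, cell in enumerate(row[1:]):
            v = float(cell) if cell.strip() else 0.0
            matrix[header.index(i)][col] = v
    diagram = load_diagram(matrix, states=header)
    for a, lab_a in enumerate(header):
        for b, lab_b in enumerate(header):
            if matrix[a][b]:
                values[rate_name(lab_a, lab_b)] = matrix[a][b]
    return diagram, values


def write_model(
    diagram: KineticDiagram,
    path: str | Path,
    values: Mapping[str, float] | None = None,
) -> None:
    """Write a diagram (and optional numeric rates) as a JSON model file."""
    values = values or {}
    edges = []
    for i, j in diagram.directed_edges():
        ann = diagram.annotation(i, j)
        edges.append(
            {
                "from": i,
                "to": j,
                "rate": rate_name(i, j),
                "value": values.get(rate_name(i, j)),
                "process": ann.process,
                "ligand": ann.ligand,
                "side": ann.side,
                "order": ann.order,
                "concentration": ann.concentration,
            }
        )
    doc = {"states": list(diagram.states), "edges": edges}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def export_diagrams(
    diagrams: Sequence[PartialDiagram | DirectionalDiagram | FluxDiagram],
    directory: str | Path,
) -> list[Path]:
    """Write each auxiliary diagram as a plain edge-list file.

    Filenames encode family, index, and (for directional diagrams) the
    target state.  Returns the written paths; an empty family writes
    nothing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for idx, diag in enumerate(diagrams):
        if isinstance(diag, DirectionalDiagram):
            name = f"directional_{idx:04d}_target{diag.target}.edges"
            lines = [f"{i}\t{j}" for i, j in diag.edges]
        elif isinstance(diag, FluxDiagram):
            cyc = "-".join(map(str, diag.target_cycle))
            name = f"flux_{idx:04d}_cycle{cyc}.edges"
            lines = [f"{i}\t{j}\tcycle" for pair in zip(
                diag.target_cycle, diag.target_cycle[1:] + diag.target_cycle[:1]
            ) for i, j in (pair, pair[::-1])]
            lines += [f"{i}\t{j}\tfeeder" for i, j in diag.feeder_edges]
        elif isinstance(diag, PartialDiagram):
            name = f"partial_{idx:04d}.edges"
            lines = [f"{i}\t{j}" for i, j in diag.edges]
        else:
            raise DiagramError(f"cannot export {type(diag).__name__}")
        target = directory / name
        target.write_text("\n".join(lines) + "\n")
        written.append(target)
    return written
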