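"""Text format for recombination-model parameter files.

Flat sectioned key/value + table format, version 1:

.. code-block:: text

    # alicetcr-model v1
    [meta]
    name = toy-beta
    ins_model = order0

    [v_segments]
    TRBV1	TGTGCCAGCAGT

    [j_segments]
    TRBJ1	AACTATGGCTACACCTTC

    [vj_usage]
    TRBV1	TRBJ1	0.35

    [v_trim]
    *	0.35 0.25 0.20 0.12 0.08

    [j_trim]
    *	0.30 0.25 0.20 0.15 0.10

    [ins_len]
    0.10 0.18 0.22 0.20 0.14 0.09 0.07

    [ins_nt]
    0.22 0.28 0.30 0.20

Optional sections ``[d_segments]``, ``[vdj_usage]`` (three name columns),
``[d5_trim]``, ``[d3_trim]``, ``[ins_len_dj]`` enable the explicit-D mode;
``ins_model = markov1`` makes ``[ins_nt]`` a 4x4 row-stochastic matrix (rows
A, C, G, T) and requires ``[ins_nt_first]``.  Trim sections map a segment
name (or ``*`` for the default) to a deletion-length probability vector.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genmodel import GenModel, ModelError

MAGIC = "# alicetcr-model v1"


def _parse_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or (line.startswith("#") and current is None):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _seg_map(lines: list[str], section: str) -> dict[str, str]:
    out = {}
    for line in lines:
        parts = line.split()
        if len(parts) != 2:
            raise ModelError(f"[{section}]: expected 'NAME SEQUENCE', got {line!r}")
        out[parts[0]] = parts[1].upper()
    return out


def _trim_map(lines: list[str], section: str) -> dict[str, np.ndarray]:
    out = {}
    for line in lines:
        parts = line.split()
        out[parts[0]] = np.array([float(x) for x in parts[1:]])
    return out


def _vector(lines: list[str]) -> np.ndarray:
    return np.array([float(x) for ln in lines for x in ln.split()])


def load_model(path: str | Path) -> GenModel:
    """Load a GenModel from the project text format."""
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0].strip() if text.strip() else ""
    if first != MAGIC:
        raise ModelError(f"{path}: missing header line {MAGIC!r}")
    sec = _parse_sections(text)
    for required in ("v_segments", "j_segments", "ins_len", "ins_nt"):
        if required not in sec:
            raise ModelError(f"{path}: missing section [{required}]")
    meta = dict(
        (k.strip(), v.strip())
        for k, v in (ln.split("=", 1) for ln in sec.get("meta", []))
    )
    ins_model = meta.get("ins_model", "order0")
    kwargs: dict = {
        "name": meta.get("name", Path(path).stem),
        "v_segments": _seg_map(sec["v_segments"], "v_segments"),
        "j_segments": _seg_map(sec["j_segments"], "j_segments"),
        "v_trim": _trim_map(sec.get("v_trim", []), "v_trim"),
        "j_trim": _trim_map(sec.get("j_trim", []), "j_trim"),
        "ins_len": _vector(sec["ins_len"]),
    }
    if ins_model == "order0":
        kwargs["ins_nt"] = _vector(sec["ins_nt"])
    elif ins_model == "markov1":
        kwargs["ins_nt"] = _vector(sec["ins_nt"]).reshape(4, 4)
        if "ins_nt_first" not in sec:
            raise ModelError(f"{path}: markov1 model requires [ins_nt_first]")
        kwargs["ins_nt_first"] = _vector(sec["ins_nt_first"])
    else:
        raise ModelError(f"{path}: unknown ins_model {ins_model!r}")
    if "d_segments" in sec:
        kwargs["d_segments"] = _seg_map(sec["d_segments"], "d_segments")
        kwargs["d5_trim"] = _trim_map(sec.get("d5_trim", []), "d5_trim")
        kwargs["d3_trim"] = _trim_map(sec.get("d3_trim", []), "d3_trim")
        kwargs["ins_len_dj"] = _vector(sec["ins_len_dj"])
        usage = {}
        for line in sec.get("vdj_usage", []):
            v, d, j, p = line.split()
            usage[(v, d, j)] = float(p)
        kwargs["vdj_usage"] = usage
        kwargs["vj_usage"] = {
            (v, j): sum(
                p for (vv, _dd, jj), p in usage.items() if (vv, jj) == (v, j)
            )
            for (v, _d, j) in usage
        }
    else:
        usage = {}
        for line in sec.get("vj_usage", []):
            v, j, p = line.split()
            usage[(v, j)] = float(p)
        kwargs["vj_usage"] = usage
    return GenModel(**kwargs)


def save_model(model: GenModel, path: str | Path) -> None:
    """Write a GenModel in the project text format (round-trips with load)."""
    lines = [MAGIC, "", "[meta]", f"name = {model.name}",
             f"ins_model = {'markov1' if model.ins_order else 'order0'}", ""]

    def vec(v: np.ndarray) -> str:
        return " ".join(f"{x:.12g}" for x in np.atleast_1d(v).ravel())

    lines.append("[v_segments]")
    lines += [f"{n}\t{s}" for n, s in sorted(model.v_segments.items())]
    lines += ["", "[j_segments]"]
    lines += [f"{n}\t{s}" for n, s in sorted(model.j_segments.items())]
    if model.has_d:
        lines += ["", "[d_segments]"]
        lines += [f"{n}\t{s}" for n, s in sorted(model.d_segments.items())]
        lines += ["", "[vdj_usage]"]
        lines += [
            f"{v}\t{d}\t{j}\t{p:.12g}"
            for (v, d, j), p in sorted(model.vdj_usage.items())
        ]
    else:
        lines += ["", "[vj_usage]"]
        lines += [
            f"{v}\t{j}\t{p:.12g}" for (v, j), p in sorted(model.vj_usage.items())
        ]
    for attr in ("v_trim", "j_trim") + (("d5_trim", "d3_trim") if model.has_d else ()):
        lines += ["", f"[{attr}]"]
        lines += [f"{k}\t{vec(v)}" for k, v in sorted(getattr(model, attr).items())]
    lines += ["", "[ins_len]", vec(model.ins_len)]
    if model.has_d:
        lines += ["", "[ins_len_dj]", vec(model.ins_len_dj)]
    lines += ["", "[ins_nt]", vec(model.ins_nt)]
    if model.ins_nt_first is not None:
        lines += ["", "[ins_nt_first]", vec(model.ins_nt_first)]
    Path(path).write_text("\n".join(lines) + "\n")
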