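"""Tabular text serialization of model parameters.

One row per free parameter: columns ``l, i, j, a, b, value`` with ``.`` in
``j``/``b`` for single-SNP fields.  SNP indices are 1-based in the file.
Only nonzero-reference entries (a, b >= 1) are written; couplings once per
unordered pair (i < j).
"""

from __future__ import annotations

import numpy as np

from .cda import CdaParameters

__all__ = ["write_params", "read_params"]

_HEADER = "l\ti\tj\ta\tb\tvalue"


def write_params(params: CdaParameters, path) -> None:
    m, L = params.m, params.n_levels
    with open(path, "w") as fh:
        fh.write(f"# m={m} levels={L}\n")
        fh.write(_HEADER + "\n")
        for l in (0, 1):
            for i in range(m):
                for a in range(1, L):
                    fh.write(f"{l}\t{i + 1}\t.\t{a}\t.\t"
                             f"{float(params.h[l, i, a])!r}\n")
        for l in (0, 1):
            for i in range(m):
                for j in range(i + 1, m):
                    for a in range(1, L):
                        for b in range(1, L):
                            fh.write(f"{l}\t{i + 1}\t{j + 1}\t{a}\t{b}\t"
                                     f"{float(params.J[l, i, j, a, b])!r}\n")


def read_params(path) -> CdaParameters:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError("missing header line with dimensions")
        meta = dict(tok.split("=") for tok in first[1:].split())
        m, L = int(meta["m"]), int(meta["levels"])
        header = fh.readline().strip()
        if header != _HEADER:
            raise ValueError(f"unexpected column header: {header!r}")
        params = CdaParameters.zeros(m, L)
        for line in fh:
            l, i, j, a, b, value = line.rstrip("\n").split("\t")
            l, i, a = int(l), int(i) - 1, int(a)
            v = float(value)
            if j == ".":
                params.h[l, i, a] = v
            else:
                jj, bb = int(j) - 1, int(b)
                params.J[l, i, jj, a, bb] = v
                params.J[l, jj, i, bb, a] = v
    return params
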