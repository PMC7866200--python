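"""Small file helpers shared by the pipeline and the CLI."""

from __future__ import annotations

import hashlib
from pathlib import Path

__all__ = ["read_fasta", "write_fasta", "sha256_file"]


def read_fasta(path) -> dict:
    """Plain FASTA -> {record id: sequence} (id = first header token)."""
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise ValueError(f"{path}: duplicate record id {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[current].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def relative_to(path: Path, root: Path) -> str:
    return str(Path(path).resolve().relative_to(Path(root).resolve()))
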