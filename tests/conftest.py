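import numpy as np
import pytest

from introspect import ProteinRecord


@pytest.fixture
def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


@pytest.fixture
def write_fasta(tmp_path):
    """Write (id, description, sequence) triples to a FASTA file."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec in entries:
                if isinstance(rec, ProteinRecord):
                    header, seq = rec.description or rec.id, rec.sequence
                else:
                    rid, desc, seq = rec
                    header = f"{rid} {desc}".strip()
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_lines(tmp_path):
    def _write(lines, name="lines.txt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
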