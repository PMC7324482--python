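import pandas as pd
import pytest

from arescreen.are_scan import UTRRecord


@pytest.fixture
def write_fasta(tmp_path):
    """Write a FASTA file from (gene_id, sequence) pairs; returns the path."""

    def _write(entries, name="utrs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for gene_id, seq in entries:
                fh.write(f">{gene_id}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def probe_records():
    """The three Ikzf2 ARE probe sequences as UTR records."""
    from arescreen.datasets import IKZF2_ARE_PROBES

    return [UTRRecord(gene_id=name, sequence=seq) for name, seq in IKZF2_ARE_PROBES.items()]


@pytest.fixture
def toy_expression():
    """Ten genes with hand-assigned FPKM pairs covering every branch.

    Expected at defaults (min_fpkm=2, fc_updown=1.5, pseudocount=0.01):
    up = {u1, u2}; down = {d1, d2, d3}; the rest fail the abundance or
    fold-change filter.
    """
    rows = [
        ("u1", 2.0, 6.0),     # up 3-fold
        ("u2", 0.0, 4.0),     # up, zero control handled by pseudocount
        ("d1", 6.0, 2.0),     # down 3-fold
        ("d2", 3.2, 2.0),     # down ~1.6-fold
        ("d3", 8.0, 0.5),     # down 16-fold
        ("low", 1.9, 1.0),    # fails abundance (max < 2)
        ("flat", 5.0, 5.0),   # no change
        ("mild", 4.0, 3.0),   # down but < 1.5-fold
        ("mildup", 3.0, 4.0), # up but < 1.5-fold
        ("zz", 0.0, 0.0),     # unexpressed
    ]
    return pd.DataFrame(rows, columns=["gene_id", "fpkm_control", "fpkm_treatment"])
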