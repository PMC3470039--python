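import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from paralogtrace import Msa, ProteinSequence


@pytest.fixture
def toy_gff3(tmp_path):
    """Three genes on chr1 (one minus-strand, one with two isoforms)."""
    text = """##gff-version 3
chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t400\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\texon\t100\t180\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
chr1\tsrc\texon\t281\t400\t.\t+\t.\tID=g1.1.e2;Parent=g1.1
chr1\tsrc\tgene\t500\t800\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t500\t800\t.\t-\t.\tID=g2.a;Parent=g2
chr1\tsrc\texon\t500\t560\t.\t-\t.\tID=g2.a.e1;Parent=g2.a
chr1\tsrc\texon\t700\t800\t.\t-\t.\tID=g2.a.e2;Parent=g2.a
chr1\tsrc\tmRNA\t500\t800\t.\t-\t.\tID=g2.b;Parent=g2
chr1\tsrc\texon\t500\t800\t.\t-\t.\tID=g2.b.e1;Parent=g2.b
chr1\tsrc\tgene\t900\t950\t.\t+\t.\tID=g3
chr1\tsrc\tmRNA\t900\t950\t.\t+\t.\tID=g3.1;Parent=g3
chr1\tsrc\texon\t900\t950\t.\t+\t.\tID=g3.1.e1;Parent=g3.1
"""
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


@pytest.fixture
def small_msa():
    return Msa(ids=["a", "b", "c", "d"], rows=["MKVA", "MKVA", "M-VA", "MKV-"])


def protein(pid: str, residues: str) -> ProteinSequence:
    return ProteinSequence(pid, residues)
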