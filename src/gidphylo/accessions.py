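"""Named study accessions and a fetch utility for real-data mode.

The curated human and yeast exemplars of the complex are listed here by
their RefSeq/UniProt accessions. :func:`fetch_sequences` retrieves them
from NCBI E-utilities (efetch, FASTA) and therefore needs network access;
everything else in the package runs fully offline on user-supplied or
synthetic proteomes.
"""

from __future__ import annotations

import urllib.parse
import urllib.request

from .seqio_align import ProteinRecord

HUMAN_ACCESSIONS = {
    "TWA1": "NP_060366",
    "RanBPM": "NP_005484",
    "MAEA": "NP_001017405",
    "Rmnd5a": "NP_073617",
    "muskelin": "NP_037387",
    "Armc8": "NP_056211",
    "WDR26": "NP_079436",
    "c17orf39": "NP_076957",
}

YEAST_ACCESSIONS = {
    "GID8": "NP_013854",   # TWA1 homologue
    "GID1": "NP_011287",   # RanBPM homologue
    "GID9": "NP_012169",   # MAEA homologue
    "GID2": "NP_010541",   # Rmnd5 homologue
    "GID5": "NP_012247",
    "GID7": "NP_09891",
    "GID4": "NP_009663",
}

UNIPROT = {
    "TWA1": "Q9NWU2", "RanBPM": "Q96S59", "MAEA": "Q7L5Y9",
    "Rmnd5a": "Q9H871", "muskelin": "Q9UL63",
    "GID8": "P40208", "GID1": "P53076", "GID9": "P40492", "GID2": "Q12508",
}

_EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_sequences(accessions: list[str], timeout: float = 10.0) -> list[ProteinRecord]:
    """Fetch protein FASTA records for RefSeq accessions via NCBI efetch.

    Requires network access; raises ``OSError`` when the service is
    unreachable.
    """
    query = urllib.parse.urlencode({
        "db": "protein", "id": ",".join(accessions), "rettype": "fasta",
        "retmode": "text",
    })
    with urllib.request.urlopen(f"{_EFETCH}?{query}", timeout=timeout) as response:
        text = response.read().decode()
    records: list[ProteinRecord] = []
    header = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        accession = header.split()[0].split(".")[0]
        records.append(ProteinRecord(accession, "".join(chunks).upper()))

    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    return records


def fetch_exemplar(accession: str, timeout: float = 10.0) -> ProteinRecord:
    records = fetch_sequences([accession], timeout=timeout)
    if not records:
        raise ValueError(f"no record returned for {accession}")
    return records[0]
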