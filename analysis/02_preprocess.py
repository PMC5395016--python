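#!/usr/bin/env python
"""Preprocess both short-read libraries.

Quality-trims (<Q20 from both ends until two consecutive >=Q20 bases),
clips adapters, drops reads under 32 bp, and demotes lone survivors of
broken pairs to "unpaired". Writes the surviving reads under
scratch/study/prepped/ and the per-library stage counts (the layout of
a library-processing table) under results/.
"""

from pathlib import Path

import pandas as pd

from refgrade.config import ILLUMINA_ADAPTERS
from refgrade.readprep import (
    PrepStats, preprocess_pairs, preprocess_single, read_fastq, write_fastq,
)

IN = Path("scratch/study")
OUT = IN / "prepped"
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stats = {"ds1": PrepStats(), "ds2": PrepStats()}

    kept = preprocess_single(read_fastq(IN / "ds1.fastq"), ILLUMINA_ADAPTERS,
                             stats=stats["ds1"])
    write_fastq(OUT / "ds1.fastq", kept)

    pairs = zip(read_fastq(IN / "ds2_1.fastq", "mate1"),
                read_fastq(IN / "ds2_2.fastq", "mate2"))
    m1, m2, unpaired = [], [], []
    for result in preprocess_pairs(pairs, ILLUMINA_ADAPTERS, stats=stats["ds2"]):
        if len(result) == 2:
            m1.append(result[0])
            m2.append(result[1])
        else:
            unpaired.append(result[0])
    write_fastq(OUT / "ds2_1.fastq", m1)
    write_fastq(OUT / "ds2_2.fastq", m2)
    write_fastq(OUT / "ds2_unpaired.fastq", unpaired)

    table = pd.DataFrame(
        [{"library": lib, **st.as_row()} for lib, st in stats.items()]
    )
    table.to_csv(RESULTS / "02_preprocessing.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
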