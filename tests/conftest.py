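import numpy as np
import pytest

from sisterhap import datasets
from sisterhap.hap_table_io import HaplotypeTable


@pytest.fixture
def il13():
    """IL-13 breast-cancer haplotype counts (560 cases / 354 controls)."""
    return datasets.il13_breast_cancer()


@pytest.fixture
def il13_file(tmp_path, il13):
    path = tmp_path / "il13.tsv"
    lines = ["#sites: " + ",".join(il13.site_ids), "haplotype\tcase_count\tcontrol_count"]
    lines += [f"{r.haplotype}\t{r.case_count:g}\t{r.control_count:g}" for r in il13.rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def four_site_table():
    """Synthetic 4-site table whose every triplet shows all 8 classes."""
    rng = np.random.default_rng(2024)
    haps = [
        "".join(h)
        for h in __import__("itertools").product("AC", "GT", "CA", "TG")
    ]
    case = rng.integers(5, 120, size=16)
    ctrl = rng.integers(5, 120, size=16)
    return HaplotypeTable.from_counts(
        ["s1", "s2", "s3", "s4"],
        list(zip(haps, case.astype(float), ctrl.astype(float))),
    )


@pytest.fixture
def six_class_table():
    """3-site table with only 6 observed haplotype classes (not RD-testable)."""
    return HaplotypeTable.from_counts(
        ["x1", "x2", "x3"],
        [
            ("ACG", 120, 100),
            ("CTA", 80, 90),
            ("ACA", 30, 20),
            ("CTG", 25, 15),
            ("ATA", 10, 5),
            ("CCG", 8, 12),
        ],
    )
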