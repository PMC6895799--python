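"""Shared fixtures: the published 52-locus pea aphid validation panel
(per-locus N / Na / FM / PIC from fragment-length genotyping) and a
seeded synthetic multi-sample transcript set."""

import pytest

from polyssr import LocusStats, make_transcript_set

# Per-locus marker statistics for the 52 pea aphid EST-SSR loci used to
# validate flank-keyed mining: locus, N genotyped, allele count, major
# allele frequency, PIC.
PEA_APHID_PANEL = """\
3	12	5	0.4167	0.5748
4	18	6	0.5278	0.6194
5	20	7	0.4250	0.7164
6	18	6	0.3333	0.7444
7	14	3	0.6786	0.4090
8	17	9	0.2059	0.8313
9	21	6	0.4286	0.7006
10	12	6	0.2917	0.7517
13	16	9	0.2813	0.8122
14	18	8	0.4444	0.7118
15	16	1	1.0000	0.0000
16	16	7	0.4375	0.7081
17	15	3	0.8333	0.2604
18	21	8	0.2381	0.8207
19	14	5	0.4643	0.6469
21	16	2	0.6250	0.3589
22	11	5	0.5000	0.6257
23	11	6	0.3182	0.7436
27	17	4	0.6176	0.5239
29	13	6	0.3462	0.6874
31	11	11	0.2273	0.8595
33	16	2	0.9375	0.1103
34	12	3	0.4583	0.5697
35	18	4	0.4722	0.5851
38	17	4	0.6176	0.5269
39	17	8	0.2647	0.7888
40	20	1	1.0000	0.0000
41	10	7	0.3500	0.7700
43	12	8	0.2917	0.8013
46	17	5	0.3235	0.7130
47	16	1	1.0000	0.0000
48	13	7	0.4231	0.6867
49	16	2	0.8750	0.1948
51	14	5	0.3214	0.7248
52	20	4	0.4500	0.5249
53	14	6	0.3929	0.7072
101	15	3	0.7667	0.3227
102	15	12	0.2000	0.8685
108	12	7	0.2917	0.7614
109	16	3	0.8438	0.2478
110	15	6	0.4333	0.6675
112	17	9	0.2353	0.8319
113	15	3	0.8333	0.2710
114	15	9	0.3667	0.7762
116	9	3	0.7222	0.3709
117	9	7	0.2778	0.8053
119	12	8	0.2500	0.7957
121	18	5	0.2778	0.7429
122	17	2	0.8824	0.1861
128	11	5	0.3182	0.7319
131	18	5	0.3056	0.7165
132	18	1	1.0000	0.0000
"""


def panel_stats() -> list[LocusStats]:
    stats = []
    for line in PEA_APHID_PANEL.strip().splitlines():
        locus, n, na, fm, pic_val = line.split("\t")
        stats.append(
            LocusStats(locus_id=locus, N=int(n), Na=int(na),
                       FM=float(fm), PIC=float(pic_val))
        )
    return stats


@pytest.fixture(scope="session")
def validation_panel() -> list[LocusStats]:
    return panel_stats()


@pytest.fixture(scope="session")
def planted_set():
    """Default study design: 6 samples, 20 planted loci (12 variable)."""
    return make_transcript_set(seed=42)
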