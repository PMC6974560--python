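# Synthetic amino-acid biosynthesis cost table (example values, not measured).
# Column contract: residue = one-letter code; atp_cost = ATP consumed to
# synthesise one molecule de novo from glucose; n_carbon = carbon atoms per
# residue as incorporated in a peptide.  Replace atp_cost with a literature
# table for real analyses.
residue	atp_cost	n_carbon
A	11.7	3
R	27.3	6
N	14.7	4
D	12.7	4
C	24.7	3
E	15.3	5
Q	16.3	5
G	11.7	2
H	38.3	6
I	32.3	6
L	27.3	6
K	30.3	6
M	34.3	5
F	52.0	9
P	20.3	5
S	11.7	3
T	18.7	4
W	74.3	11
Y	50.0	9
V	23.3	5
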