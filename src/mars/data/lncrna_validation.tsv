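peptide	score	allele	m_rank	validated
MTMSTILSKK	99.8	HLA-A*11:01	0.12	yes
KVHVFLVKK	99.7	HLA-A*03:01	0.029	yes
MTMSTILSK	99.2	HLA-A*11:01	0.008	yes
KQLNKQLIK	98.3	HLA-A*03:01	0.053	yes
ALRAVTLTAK	97.9	HLA-A*03:01	0.099	yes
VIFSGIRSL	95.4	HLA-A*02:01	0.081	yes
TELKAWKI	95.2	HLA-B*37:01	0.138	no
IPHGEIPDTSA	94.9	HLA-B*56:01	0.064	yes
VLLSIFIEHL	94.2	HLA-A*02:01	1.15	no
KTKIITGSK	94.1	HLA-A*03:01	0.192	yes
LPYIKWTI	93.6	HLA-B*51:01	0.076	yes
IIYFCLHKI	93.4	HLA-A*02:01	0.629	no
SLSILSLKV	92.9	HLA-B*13:02	0.164	no
LPNFARII	92.6	HLA-B*07:02	0.29	no
RQAPALRHL	92.5	HLA-C*06:02	0.133	yes
IISASKVIL	92.3	HLA-A*02:01	0.617	no
VTIFQNRVK	92.0	HLA-A*11:01	0.575	yes
IRNVKIYLI	91.2	HLA-C*06:02	0.09	no
LSSTLNKQI	90.1	HLA-C*02:02	1.143	no
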