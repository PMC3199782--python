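# Synthetic 315-gene nuclear-encoded mitochondria-targeted reference set.
# Category sizes follow the published census; gene ids are placeholders
# (nemt0001..) to be substituted with real gene-level content when available.
# mtSSB is included under DNA_synthesis so its absence can be reported.
nemt0001	OXPHOS
nemt0002	OXPHOS
nemt0003	OXPHOS
nemt0004	OXPHOS
nemt0005	OXPHOS
nemt0006	OXPHOS
nemt0007	OXPHOS
nemt0008	OXPHOS
nemt0009	OXPHOS
nemt0010	OXPHOS
nemt0011	OXPHOS
nemt0012	OXPHOS
nemt0013	OXPHOS
nemt0014	OXPHOS
nemt0015	OXPHOS
nemt0016	OXPHOS
nemt0017	OXPHOS
nemt0018	OXPHOS
nemt0019	OXPHOS
nemt0020	OXPHOS
nemt0021	OXPHOS
nemt0022	OXPHOS
nemt0023	OXPHOS
nemt0024	OXPHOS
nemt0025	OXPHOS
nemt0026	OXPHOS
nemt0027	OXPHOS
nemt0028	OXPHOS
nemt0029	OXPHOS
nemt0030	OXPHOS
nemt0031	OXPHOS
nemt0032	OXPHOS
nemt0033	OXPHOS
nemt0034	OXPHOS
nemt0035	OXPHOS
nemt0036	OXPHOS
nemt0037	OXPHOS
nemt0038	OXPHOS
nemt0039	OXPHOS
nemt0040	OXPHOS
nemt0041	OXPHOS
nemt0042	OXPHOS
nemt0043	OXPHOS
nemt0044	OXPHOS
nemt0045	OXPHOS
nemt0046	OXPHOS
nemt0047	OXPHOS
nemt0048	OXPHOS
nemt0049	OXPHOS
nemt0050	OXPHOS
nemt0051	OXPHOS
nemt0052	OXPHOS
nemt0053	OXPHOS
nemt0054	OXPHOS
nemt0055	OXPHOS
nemt0056	OXPHOS
nemt0057	OXPHOS
nemt0058	OXPHOS
nemt0059	OXPHOS
nemt0060	OXPHOS
nemt0061	OXPHOS
nemt0062	OXPHOS
nemt0063	OXPHOS
nemt0064	OXPHOS
nemt0065	OXPHOS
nemt0066	OXPHOS
nemt0067	OXPHOS
nemt0068	OXPHOS
nemt0069	OXPHOS
nemt0070	OXPHOS
nemt0071	OXPHOS
nemt0072	OXPHOS
nemt0073	OXPHOS
nemt0074	OXPHOS
nemt0075	other_metabolic
nemt0076	other_metabolic
nemt0077	other_metabolic
nemt0078	other_metabolic
nemt0079	other_metabolic
nemt0080	other_metabolic
nemt0081	other_metabolic
nemt0082	other_metabolic
nemt0083	other_metabolic
nemt0084	other_metabolic
nemt0085	other_metabolic
nemt0086	other_metabolic
nemt0087	other_metabolic
nemt0088	other_metabolic
nemt0089	other_metabolic
nemt0090	other_metabolic
nemt0091	other_metabolic
nemt0092	other_metabolic
nemt0093	other_metabolic
nemt0094	other_metabolic
nemt0095	other_metabolic
nemt0096	other_metabolic
nemt0097	other_metabolic
nemt0098	other_metabolic
nemt0099	other_metabolic
nemt0100	other_metabolic
nemt0101	other_metabolic
nemt0102	other_metabolic
nemt0103	other_metabolic
nemt0104	other_metabolic
nemt0105	other_metabolic
nemt0106	other_metabolic
nemt0107	other_metabolic
nemt0108	other_metabolic
nemt0109	other_metabolic
nemt0110	other_metabolic
nemt0111	other_metabolic
nemt0112	other_metabolic
nemt0113	other_metabolic
nemt0114	other_metabolic
nemt0115	other_metabolic
nemt0116	other_metabolic
nemt0117	other_metabolic
nemt0118	other_metabolic
nemt0119	other_metabolic
nemt0120	other_metabolic
nemt0121	other_metabolic
nemt0122	other_metabolic
nemt0123	other_metabolic
nemt0124	other_metabolic
nemt0125	other_metabolic
nemt0126	other_metabolic
nemt0127	other_metabolic
nemt0128	other_metabolic
nemt0129	other_metabolic
nemt0130	other_metabolic
nemt0131	other_metabolic
nemt0132	other_metabolic
nemt0133	other_metabolic
nemt0134	other_metabolic
nemt0135	other_metabolic
nemt0136	other_metabolic
nemt0137	other_metabolic
nemt0138	other_metabolic
nemt0139	other_metabolic
nemt0140	other_metabolic
nemt0141	other_metabolic
nemt0142	other_metabolic
nemt0143	other_metabolic
nemt0144	other_metabolic
nemt0145	other_metabolic
nemt0146	other_metabolic
nemt0147	other_metabolic
nemt0148	other_metabolic
nemt0149	other_metabolic
nemt0150	other_metabolic
nemt0151	other_metabolic
nemt0152	other_metabolic
nemt0153	other_metabolic
nemt0154	other_metabolic
nemt0155	other_metabolic
nemt0156	other_metabolic
nemt0157	other_metabolic
nemt0158	other_metabolic
nemt0159	other_metabolic
nemt0160	other_metabolic
nemt0161	other_metabolic
nemt0162	protein_synthesis
nemt0163	protein_synthesis
nemt0164	protein_synthesis
nemt0165	protein_synthesis
nemt0166	protein_synthesis
nemt0167	protein_synthesis
nemt0168	protein_synthesis
nemt0169	protein_synthesis
nemt0170	protein_synthesis
nemt0171	protein_synthesis
nemt0172	protein_synthesis
nemt0173	protein_synthesis
nemt0174	protein_synthesis
nemt0175	protein_synthesis
nemt0176	protein_synthesis
nemt0177	protein_synthesis
nemt0178	protein_synthesis
nemt0179	protein_synthesis
nemt0180	protein_synthesis
nemt0181	protein_synthesis
nemt0182	protein_synthesis
nemt0183	protein_synthesis
nemt0184	protein_synthesis
nemt0185	protein_synthesis
nemt0186	protein_synthesis
nemt0187	protein_synthesis
nemt0188	protein_synthesis
nemt0189	protein_synthesis
nemt0190	protein_synthesis
nemt0191	protein_synthesis
nemt0192	protein_synthesis
nemt0193	protein_synthesis
nemt0194	protein_synthesis
nemt0195	protein_synthesis
nemt0196	protein_synthesis
nemt0197	protein_synthesis
nemt0198	protein_synthesis
nemt0199	protein_synthesis
nemt0200	protein_synthesis
nemt0201	protein_synthesis
nemt0202	protein_synthesis
nemt0203	protein_synthesis
nemt0204	protein_synthesis
nemt0205	protein_synthesis
nemt0206	protein_synthesis
nemt0207	protein_synthesis
nemt0208	protein_synthesis
nemt0209	protein_synthesis
nemt0210	protein_synthesis
nemt0211	protein_synthesis
nemt0212	protein_synthesis
nemt0213	protein_synthesis
nemt0214	protein_synthesis
nemt0215	protein_synthesis
nemt0216	protein_synthesis
nemt0217	protein_synthesis
nemt0218	protein_synthesis
nemt0219	protein_synthesis
nemt0220	protein_synthesis
nemt0221	protein_synthesis
nemt0222	protein_synthesis
nemt0223	protein_synthesis
nemt0224	protein_synthesis
nemt0225	protein_synthesis
nemt0226	protein_synthesis
nemt0227	protein_synthesis
nemt0228	protein_synthesis
nemt0229	protein_synthesis
nemt0230	protein_synthesis
nemt0231	protein_synthesis
nemt0232	protein_synthesis
nemt0233	protein_synthesis
nemt0234	protein_synthesis
nemt0235	protein_synthesis
nemt0236	protein_synthesis
nemt0237	protein_synthesis
nemt0238	protein_synthesis
nemt0239	protein_synthesis
nemt0240	protein_synthesis
nemt0241	protein_synthesis
nemt0242	protein_synthesis
nemt0243	protein_synthesis
nemt0244	protein_synthesis
nemt0245	protein_synthesis
nemt0246	protein_synthesis
nemt0247	protein_synthesis
nemt0248	protein_synthesis
nemt0249	protein_synthesis
nemt0250	protein_synthesis
nemt0251	protein_synthesis
nemt0252	protein_synthesis
nemt0253	protein_synthesis
nemt0254	protein_synthesis
nemt0255	protein_synthesis
nemt0256	protein_synthesis
nemt0257	protein_synthesis
nemt0258	protein_synthesis
nemt0259	protein_synthesis
nemt0260	protein_synthesis
nemt0261	protein_synthesis
nemt0262	protein_synthesis
nemt0263	protein_synthesis
nemt0264	protein_synthesis
nemt0265	protein_synthesis
nemt0266	protein_synthesis
nemt0267	protein_synthesis
nemt0268	protein_synthesis
nemt0269	protein_synthesis
nemt0270	protein_synthesis
nemt0271	protein_synthesis
nemt0272	protein_synthesis
nemt0273	protein_synthesis
nemt0274	protein_synthesis
mtSSB	DNA_synthesis
nemt0276	DNA_synthesis
nemt0277	DNA_synthesis
nemt0278	DNA_synthesis
nemt0279	DNA_synthesis
nemt0280	DNA_synthesis
nemt0281	DNA_synthesis
nemt0282	DNA_synthesis
nemt0283	DNA_synthesis
nemt0284	DNA_synthesis
nemt0285	DNA_synthesis
nemt0286	DNA_synthesis
nemt0287	DNA_synthesis
nemt0288	DNA_synthesis
nemt0289	DNA_synthesis
nemt0290	transport_cell_rescue
nemt0291	transport_cell_rescue
nemt0292	transport_cell_rescue
nemt0293	transport_cell_rescue
nemt0294	transport_cell_rescue
nemt0295	transport_cell_rescue
nemt0296	transport_cell_rescue
nemt0297	transport_cell_rescue
nemt0298	transport_cell_rescue
nemt0299	transport_cell_rescue
nemt0300	transport_cell_rescue
nemt0301	transport_cell_rescue
nemt0302	transport_cell_rescue
nemt0303	transport_cell_rescue
nemt0304	transport_cell_rescue
nemt0305	transport_cell_rescue
nemt0306	transport_cell_rescue
nemt0307	transport_cell_rescue
nemt0308	transport_cell_rescue
nemt0309	transport_cell_rescue
nemt0310	transport_cell_rescue
nemt0311	transport_cell_rescue
nemt0312	miscellaneous
nemt0313	miscellaneous
nemt0314	miscellaneous
nemt0315	miscellaneous
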