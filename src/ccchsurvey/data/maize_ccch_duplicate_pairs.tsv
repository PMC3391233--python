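# Reported Ka/Ks analysis of the 17 duplicated paralog pairs of the maize
# CCCH zinc-finger family (ZmC3H genes, B73 genome).  Ka and Ks are the
# published estimates and serve as inputs; ratio, selection, date and
# duplicate type are the published report columns used for validation of
# the recomputation (lambda = 6.5e-9 synonymous substitutions/site/year).
gene_a	gene_b	ka	ks	reported_ratio	reported_purifying	reported_date_mya	duplicate_type
ZmC3H14	ZmC3H46	0.044	0.143	0.308	Yes	11	Segmental
ZmC3H13	ZmC3H47	0.063	0.168	0.375	Yes	12.92	Segmental
ZmC3H16	ZmC3H57	0.04	0.201	0.199	Yes	15.46	Segmental
ZmC3H20	ZmC3H55	0.205	0.244	0.84	Yes	18.77	Segmental
ZmC3H6	ZmC3H67	0.066	0.24	0.275	Yes	18.46	Segmental
ZmC3H37	ZmC3H60	0.134	0.131	1.023	No	10.08	Segmental
ZmC3H7	ZmC3H66	0.044	0.175	0.251	Yes	13.46	Segmental
ZmC3H29	ZmC3H36	0.014	0.169	0.083	Yes	13	Segmental
ZmC3H12	ZmC3H51	0.059	0.172	0.343	Yes	13.23	Segmental
ZmC3H39	ZmC3H53	0.061	0.178	0.343	Yes	13.69	Segmental
ZmC3H4	ZmC3H28	0.025	0.23	0.109	Yes	17.69	Segmental
ZmC3H2	ZmC3H61	0.031	0.205	0.151	Yes	15.77	Segmental
ZmC3H18	ZmC3H56	0.095	0.067	1.418	No	5.15	Segmental
ZmC3H23	ZmC3H64	0.067	0.359	0.187	Yes	27.62	Segmental
ZmC3H30	ZmC3H35	0.053	0.156	0.34	Yes	12	Segmental
ZmC3H13	ZmC3H14	0.262	0.818	0.32	Yes	62.92	Tandem
ZmC3H46	ZmC3H47	0.292	0.965	0.303	Yes	74.23	Tandem
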