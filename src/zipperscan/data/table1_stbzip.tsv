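gene_name	locus_id	group	synonym
StbZIP2	Soltu.DM.01G005870	A
StbZIP3	Soltu.DM.01G006940	A
StbZIP12	Soltu.DM.10G030340	A	ABL2
StbZIP13	Soltu.DM.04G027170	A
StbZIP14	Soltu.DM.02G023460	A
StbZIP27	Soltu.DM.02G005680	A
StbZIP35	Soltu.DM.11G016910	A	AREB4
StbZIP36	Soltu.DM.04G033590	A	AREB2
StbZIP37	Soltu.DM.10G015000	A	AREB3
StbZIP38	Soltu.DM.01G047570	A	AREB1
StbZIP39	Soltu.DM.09G003620	A	ABI5
StbZIP40	Soltu.DM.01G043800	A
StbZIP66	Soltu.DM.10G025990	A	ABL1
StbZIP17	Soltu.DM.10G029910	B
StbZIP28	Soltu.DM.04G021020	B
StbZIP33	Soltu.DM.04G020920	B
StbZIP67	Soltu.DM.08G019490	B
StbZIP70	Soltu.DM.08G019530	B
StbZIP71	Soltu.DM.08G019590	B
StbZIP9	Soltu.DM.08G002700	C
StbZIP10	Soltu.DM.08G008380	C
StbZIP63	Soltu.DM.01G036510	C
StbZIP1	Soltu.DM.01G005540	D
StbZIP20	Soltu.DM.11G019010	D
StbZIP21	Soltu.DM.06G029750	D
StbZIP43	Soltu.DM.04G022450	D
StbZIP45	Soltu.DM.10G026630	D
StbZIP46	Soltu.DM.05G002740	D
StbZIP47	Soltu.DM.04G007700	D
StbZIP50	Soltu.DM.12G007270	D
StbZIP57	Soltu.DM.04G028540	D
StbZIP65	Soltu.DM.10G029320	D
StbZIP74	Soltu.DM.10G027000	D
StbZIP80	Soltu.DM.11G021800	D
StbZIP34	Soltu.DM.12G028390	E
StbZIP61	Soltu.DM.07G020410	E
StbZIP64	Soltu.DM.07G023890	E
StbZIP76	Soltu.DM.10G011180	E
StbZIP77	Soltu.DM.11G012470	E
StbZIP78	Soltu.DM.01G042790	E
StbZIP79	Soltu.DM.11G007430	E
StbZIP19	Soltu.DM.10G017560	F
StbZIP23	Soltu.DM.01G051130	F
StbZIP16	Soltu.DM.08G003670	G
StbZIP24	Soltu.DM.02G006750	G
StbZIP41	Soltu.DM.02G025470	G
StbZIP54	Soltu.DM.05G019830	G
StbZIP55	Soltu.DM.01G034570	G
StbZIP68	Soltu.DM.08G021830	G
StbZIP56	Soltu.DM.08G011730	H
StbZIP18	Soltu.DM.06G011870	I
StbZIP29	Soltu.DM.01G050330	I
StbZIP30	Soltu.DM.04G036300	I
StbZIP48	Soltu.DM.04G026570	I
StbZIP49	Soltu.DM.06G017610	I
StbZIP51	Soltu.DM.04G026750	I
StbZIP52	Soltu.DM.06G011430	I
StbZIP69	Soltu.DM.06G014230	I
StbZIP62	Soltu.DM.10G024960	J
StbZIP72	Soltu.DM.09G003280	J
StbZIP60	Soltu.DM.04G038150	K
StbZIP25	Soltu.DM.03G005150	N
StbZIP26	Soltu.DM.03G005200	N
StbZIP59	Soltu.DM.06G032460	N
StbZIP75	Soltu.DM.11G017940	N
StbZIP4	Soltu.DM.01G024850	S
StbZIP5	Soltu.DM.03G005290	S
StbZIP6	Soltu.DM.02G027390	S
StbZIP7	Soltu.DM.04G032270	S
StbZIP8	Soltu.DM.01G040220	S
StbZIP11	Soltu.DM.02G024680	S
StbZIP15	Soltu.DM.01G049720	S
StbZIP22	Soltu.DM.02G006290	S
StbZIP31	Soltu.DM.03G006600	S
StbZIP32	Soltu.DM.04G000200	S
StbZIP42	Soltu.DM.02G030370	S
StbZIP44	Soltu.DM.04G035840	S
StbZIP53	Soltu.DM.06G000140	S
StbZIP58	Soltu.DM.05G001710	S
StbZIP73	Soltu.DM.10G016240	S
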