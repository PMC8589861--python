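symbol	subunit
AURKAIP1	SSU
CHCHD1	SSU
DAP3	SSU
MRPS2	SSU
MRPS5	SSU
MRPS6	SSU
MRPS7	SSU
MRPS9	SSU
MRPS10	SSU
MRPS11	SSU
MRPS12	SSU
MRPS14	SSU
MRPS15	SSU
MRPS16	SSU
MRPS17	SSU
MRPS18B	SSU
MRPS18C	SSU
MRPS21	SSU
MRPS22	SSU
MRPS23	SSU
MRPS24	SSU
MRPS25	SSU
MRPS26	SSU
MRPS27	SSU
MRPS28	SSU
MRPS31	SSU
MRPS33	SSU
MRPS34	SSU
MRPS35	SSU
PTCD3	SSU
GADD45GIP1	LSU
ICT1	LSU
MRPL1	LSU
MRPL2	LSU
MRPL3	LSU
MRPL4	LSU
MRPL9	LSU
MRPL10	LSU
MRPL11	LSU
MRPL12	LSU
MRPL13	LSU
MRPL14	LSU
MRPL15	LSU
MRPL16	LSU
MRPL17	LSU
MRPL18	LSU
MRPL19	LSU
MRPL20	LSU
MRPL21	LSU
MRPL22	LSU
MRPL23	LSU
MRPL24	LSU
MRPL27	LSU
MRPL28	LSU
MRPL30	LSU
MRPL32	LSU
MRPL33	LSU
MRPL34	LSU
MRPL35	LSU
MRPL36	LSU
MRPL37	LSU
MRPL38	LSU
MRPL39	LSU
MRPL40	LSU
MRPL41	LSU
MRPL42	LSU
MRPL43	LSU
MRPL44	LSU
MRPL45	LSU
MRPL46	LSU
MRPL47	LSU
MRPL48	LSU
MRPL49	LSU
MRPL50	LSU
MRPL51	LSU
MRPL52	LSU
MRPL53	LSU
MRPL54	LSU
MRPL55	LSU
MRPL57	LSU
MRPS18A	LSU
MRPS30	LSU
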