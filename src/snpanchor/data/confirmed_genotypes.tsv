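cell	Chr21_37664570:G->T	Chr4_15733256:C->T	Chr5_149497105:G->A	Chr6_150570076:T->C	Chr6_33231195:G->C	Chr1_144946864:T->C	Chr3_116163658:A->C	Chr6_10891886:G->A	Chr6_150570077:C->T	Chr17_29563085:T->G	Chr1_985450:G->A	Chr19_3938820:G->T	Chr17_2140011:A->T	Chr5_149497107:G->A	Chr19_35832953:C->T	Chr16_66886566:C->T	Chr1_157494385:C->A	Chr6_90432584:A->T
LC-1	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-10	0	0	0	0	1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-100	1	-1	-1	-1	-1	0	0	0	0	0	0	1	0	0	NA	NA	NA	NA
LC-11	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-12	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-13	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-14	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-15	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-16	1	0	0	0	0	0	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-17	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-18	0	0	0	0	0	0	0	0	0	0	0	1	1	0	NA	NA	NA	NA
LC-19	0	0	0	0	1	-1	0	1	0	0	0	0	0	0	NA	NA	NA	NA
LC-2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-20	0	0	0	0	0	0	1	0	0	0	0	1	0	0	NA	NA	NA	NA
LC-21	1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-22	0	0	0	1	-1	-1	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-23	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-24	0	1	0	0	0	0	0	0	0	1	0	0	0	0	NA	NA	NA	NA
LC-25	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-26	0	0	0	0	1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-27	0	0	0	0	0	1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-28	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-29	1	0	0	0	0	0	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-3	1	0	0	1	0	1	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-30	1	1	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-31	0	1	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-33	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-34	1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-35	0	1	0	-1	0	0	0	-1	-1	0	0	0	0	0	NA	NA	NA	NA
LC-36	1	0	1	0	0	1	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-37	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-38	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-39	0	1	0	0	0	-1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-40	0	0	1	0	0	1	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-41	0	0	1	0	0	0	0	0	0	0	0	1	0	1	NA	NA	NA	NA
LC-43	0	0	0	0	-1	0	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-44	0	0	0	0	0	1	0	0	0	-1	0	0	0	0	NA	NA	NA	NA
LC-45	0	0	0	1	0	0	0	0	1	0	0	0	0	1	NA	NA	NA	NA
LC-47	1	0	0	1	0	0	0	0	1	0	-1	0	0	0	NA	NA	NA	NA
LC-48	0	0	0	1	1	0	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-49	0	0	0	0	-1	-1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-5	1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-50	0	0	0	1	0	0	1	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-52	1	0	0	1	0	-1	0	0	1	0	0	1	0	0	NA	NA	NA	NA
LC-54	1	0	0	0	1	0	1	0	0	0	0	1	1	1	NA	NA	NA	NA
LC-56	1	0	0	0	1	0	0	0	0	0	0	1	0	0	NA	NA	NA	NA
LC-6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-60	0	0	0	1	0	0	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-61	0	0	0	0	1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-63	0	0	0	0	0	0	0	0	0	0	0	1	0	1	NA	NA	NA	NA
LC-66	1	0	0	1	0	0	0	0	1	0	0	1	0	0	NA	NA	NA	NA
LC-69	1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-7	0	1	0	0	-1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-70	0	0	0	0	0	1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-71	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-72	-1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-73	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-74	1	0	0	0	0	0	1	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-75	1	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-76	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-77	0	0	0	0	1	0	0	0	0	0	0	1	0	0	NA	NA	NA	NA
LC-78	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-79	0	0	0	0	-1	-1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-8	0	1	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-80	1	1	0	0	1	0	0	0	0	0	0	1	-1	1	NA	NA	NA	NA
LC-81	0	0	0	0	0	0	0	0	0	0	0	1	0	0	NA	NA	NA	NA
LC-82	0	0	0	1	0	0	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-83	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-84	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-85	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-86	1	0	0	1	0	0	0	0	1	0	0	0	0	0	NA	NA	NA	NA
LC-87	-1	0	0	0	0	1	1	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-88	0	0	0	0	-1	-1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-89	0	0	0	0	0	1	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-9	1	1	1	0	0	0	0	0	0	0	0	0	0	1	NA	NA	NA	NA
LC-90	0	0	0	1	0	0	0	0	1	0	0	0	0	1	NA	NA	NA	NA
LC-91	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-93	1	0	0	0	1	0	1	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-94	0	0	0	0	1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
LC-97	0	1	0	0	-1	0	0	0	0	0	0	0	0	0	NA	NA	NA	NA
RC-1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	1
RC-2	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	0	0	1
RC-3	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	0	0	0
RC-4	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	-1	0	1
RC-5	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	1	0	0
RC-6	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	1
RC-7	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	1
RC-8	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	0
RC-9	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	0
RC-10	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	0	-1	0
RC-11	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	0	0	0
RC-12	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	0	0	0
RC-13	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	1	1
RC-14	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	0
RC-16	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	0	1
RC-18	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	0	0	1
RC-19	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	-1	1	1	0
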