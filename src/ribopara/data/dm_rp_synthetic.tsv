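accession	gene_symbol	subunit	group_id	role
RpS14a	RpS14a	SSU	RpS14	canonical
RpS14b	RpS14b	SSU	RpS14	alternative
RpS19a	RpS19a	SSU	RpS19	canonical
RpS19b	RpS19b	SSU	RpS19	alternative
RpS5a	RpS5a	SSU	RpS5	canonical
RpS5b	RpS5b	SSU	RpS5	alternative
RpS15Aa	RpS15Aa	SSU	RpS15A	canonical
RpS15Ab	RpS15Ab	SSU	RpS15A	alternative
RpS10b	RpS10b	SSU	RpS10	canonical
RpS10a	RpS10a	SSU	RpS10	alternative
RpS28b	RpS28b	SSU	RpS28	canonical
RpS28a	RpS28a	SSU	RpS28	alternative
RpL22	RpL22	LSU	RpL22	canonical
RpL22-like	RpL22-like	LSU	RpL22	alternative
RpL37a	RpL37a	LSU	RpL37	canonical
RpL37b	RpL37b	LSU	RpL37	alternative
RpL24	RpL24	LSU	RpL24	canonical
RpL24-like	RpL24-like	LSU	RpL24	alternative
RpL7	RpL7	LSU	RpL7	canonical
RpL7-like	RpL7-like	LSU	RpL7	alternative
RpLP0	RpLP0	LSU	RpLP0	canonical
RpLP0-like	RpLP0-like	LSU	RpLP0	alternative
RpL10Aa	RpL10Aa	LSU	RpL10A	canonical
RpL10Ab	RpL10Ab	LSU	RpL10A	alternative
RpL34a	RpL34a	LSU	RpL34	canonical
RpL34b	RpL34b	LSU	RpL34	alternative
RpS2	RpS2	SSU		none
RpS3	RpS3	SSU		none
RpS3A	RpS3A	SSU		none
RpS4	RpS4	SSU		none
RpS6	RpS6	SSU		none
RpS7	RpS7	SSU		none
RpS8	RpS8	SSU		none
RpS9	RpS9	SSU		none
RpS11	RpS11	SSU		none
RpS12	RpS12	SSU		none
RpS13	RpS13	SSU		none
RpS15	RpS15	SSU		none
RpS16	RpS16	SSU		none
RpS17	RpS17	SSU		none
RpS18	RpS18	SSU		none
RpS20	RpS20	SSU		none
RpS21	RpS21	SSU		none
RpS23	RpS23	SSU		none
RpS24	RpS24	SSU		none
RpS25	RpS25	SSU		none
RpS26	RpS26	SSU		none
RpS27	RpS27	SSU		none
RpS27A	RpS27A	SSU		none
RpS29	RpS29	SSU		none
RpS30	RpS30	SSU		none
RpSA	RpSA	SSU		none
RACK1	RACK1	SSU		none
RpL3	RpL3	LSU		none
RpL4	RpL4	LSU		none
RpL5	RpL5	LSU		none
RpL6	RpL6	LSU		none
RpL7A	RpL7A	LSU		none
RpL8	RpL8	LSU		none
RpL9	RpL9	LSU		none
RpL10	RpL10	LSU		none
RpL11	RpL11	LSU		none
RpL12	RpL12	LSU		none
RpL13	RpL13	LSU		none
RpL13A	RpL13A	LSU		none
RpL14	RpL14	LSU		none
RpL15	RpL15	LSU		none
RpL16	RpL16	LSU		none
RpL17	RpL17	LSU		none
RpL18	RpL18	LSU		none
RpL18A	RpL18A	LSU		none
RpL19	RpL19	LSU		none
RpL21	RpL21	LSU		none
RpL23	RpL23	LSU		none
RpL23A	RpL23A	LSU		none
RpL26	RpL26	LSU		none
RpL27	RpL27	LSU		none
RpL27A	RpL27A	LSU		none
RpL28	RpL28	LSU		none
RpL29	RpL29	LSU		none
RpL30	RpL30	LSU		none
RpL31	RpL31	LSU		none
RpL32	RpL32	LSU		none
RpL35	RpL35	LSU		none
RpL35A	RpL35A	LSU		none
RpL36	RpL36	LSU		none
RpL36A	RpL36A	LSU		none
RpL38	RpL38	LSU		none
RpL39	RpL39	LSU		none
RpL40	RpL40	LSU		none
RpL41	RpL41	LSU		none
RpLP1	RpLP1	LSU		none
RpLP2	RpLP2	LSU		none
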