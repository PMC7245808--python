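pt_code	pt_name	hlgt_name
10000001	Device failure	Device issues
10000002	Device malfunction	Device issues
10000003	Device use error	Device issues
10000004	Device use issue	Device issues
10000005	Wrong device used	Device issues
10000006	Device leakage	Device issues
10000011	Drug administered in wrong device	Medication errors, and other product use errors and issues
10000012	Drug administration error	Medication errors, and other product use errors and issues
10000013	Intentional device misuse	Medication errors, and other product use errors and issues
10000014	Intentional product misuse	Medication errors, and other product use errors and issues
10000015	Product use issue	Medication errors, and other product use errors and issues
10000016	Wrong technique in device usage process	Medication errors, and other product use errors and issues
10000017	Wrong technique in product usage process	Medication errors, and other product use errors and issues
10000018	Accidental overdose	Medication errors, and other product use errors and issues
10000021	Headache	Headaches
10000022	Blood glucose increased	Investigations
10000023	Hypoglycaemia	Glucose metabolism disorders
10000024	Dizziness	Neurological disorders NEC
10000025	Injection site pain	Administration site reactions
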