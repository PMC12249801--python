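cdr3	v.segm	antigen.epitope	cluster.id
CCTHRAPIWTAGWF	TRBV5	p30	C3
CCTNRAPIPWAGWF	TRBV5	p30	C3
CCTNRAPIWTAGWF	TRBV5	p30	C3
CCTNRAPIWWAGWF	TRBV5	p30	C3
CCTNWAPIWWAGWF	TRBV5	p30	C3
CSTNRAPIWTAGWF	TRBV5	p30	C3
CECTMDEPNFHDSMF	TRBV2	p30	C8
CECTMDEPNFHHFMF	TRBV2	p30	C8
CECTMDEPNFHHSMF	TRBV2	p30	C8
CEGTMDEPNFHHSMF	TRBV2	p30	C8
CEGTMDNPNFHHSMF	TRBV2	p30	C8
CCCTLAFVCHTEQF	TRBV16	p30	C11
CCCTLQFVCHTEQF	TRBV16	p30	C11
CCCTLQFVCYTEQF	TRBV16	p30	C11
CCCTLQRVCHTEQF	TRBV16	p30	C11
CICNFQFVCYTEQF	TRBV16	p30	C11
CICNLQFVCYTEQF	TRBV16	p30	C11
CICNLQFVCYTKQF	TRBV16	p30	C11
CICTLQFVCYTEQF	TRBV16	p30	C11
CMCTLQFVCYTEQF	TRBV16	p30	C11
CADSFGSQNFLYF	TRBV13-1	p30	C14
CADSFGSQNFVYF	TRBV13-1	p30	C14
CAGSFGRQNTLYF	TRBV13-1	p30	C14
CAGSFNRQNTLYF	TRBV13-1	p30	C14
CAHSFGRQNTHYF	TRBV13-1	p30	C14
CAHSFGRQNTLYF	TRBV13-1	p30	C14
CAPSFGRQNTLYF	TRBV13-1	p30	C14
CASSFGRQNDLHF	TRBV13-1	p30	C14
CASSFGRQNTLHF	TRBV13-1	p30	C14
CASSFGRQNTLVF	TRBV13-1	p30	C14
CASSFGRQNTLYF	TRBV13-1	p30	C14
CASSFGRQWTLVF	TRBV13-1	p30	C14
CASSFGRVNTLHF	TRBV13-1	p30	C14
CASSFGSQNFLYF	TRBV13-1	p30	C14
CASSFGSQNMLYF	TRBV13-1	p30	C14
CASSFGSQNTLYF	TRBV13-1	p30	C14
CAWSFGLQNTLYF	TRBV13-1	p30	C14
CAWSFGRQGTLYF	TRBV13-1	p30	C14
CAWSFGRQNDLYF	TRBV13-1	p30	C14
CAWSFGRQNTLYF	TRBV13-1	p30	C14
CAWSFRRQNTLYF	TRBV13-1	p30	C14
CAWYFRRQNTLYF	TRBV13-1	p30	C14
CAWYFRRQQTLYF	TRBV13-1	p30	C14
CAWYFRWQNTLYF	TRBV13-1	p30	C14
CQAELLWNSSMNAF	TRBV12-2	p30	C19
CQAPLLWNDSMNAF	TRBV12-2	p30	C19
CQAPLLWNGSMNAF	TRBV12-2	p30	C19
CQAPLLWNQSMNAF	TRBV12-2	p30	C19
CQAPLLWNSSMNAF	TRBV12-2	p30	C19
CQAPLNWNSSMNAF	TRBV12-2	p30	C19
CQAPLWWNSSMNAF	TRBV12-2	p30	C19
CGARGTGNTGQLYF	TRBV31	p30	C22
CGCRGTGNTGQLYF	TRBV31	p30	C22
CGFRGTGNTGMLTF	TRBV31	p30	C22
CGFRGTGNTGQLTF	TRBV31	p30	C22
CGFRGTGNTGQLYF	TRBV31	p30	C22
CGNRGMGNDGQLYF	TRBV31	p30	C22
CGNRGMGNTGQLYF	TRBV31	p30	C22
CGNRGTGNTGPLYF	TRBV31	p30	C22
CGNRGTGNTGQLYF	TRBV31	p30	C22
CGNRGTGSTGPLYF	TRBV31	p30	C22
CGTRGTGNTGQLYF	TRBV31	p30	C22
CLFRGTGNTGMLTF	TRBV31	p30	C22
CGALDIFMRKQF	TRBV13-3	p30	C25
CGTDLIFMRQQF	TRBV13-3	p30	C25
CGTGLIFMRMQF	TRBV13-3	p30	C25
CGTGLIFMRQQF	TRBV13-3	p30	C25
CGTHDRPMLMQF	TRBV13-3	p30	C25
CGTLCCMMLMQF	TRBV13-3	p30	C25
CGTLCIMMLMQF	TRBV13-3	p30	C25
CGTLCIMMLMYF	TRBV13-3	p30	C25
CGTLDFFKRMQF	TRBV13-3	p30	C25
CGTLDFFMRMQF	TRBV13-3	p30	C25
CGTLDIFMLMQF	TRBV13-3	p30	C25
CGTLDIFMRKQF	TRBV13-3	p30	C25
CGTLDIFMRMQF	TRBV13-3	p30	C25
CGTLDIMMLMQF	TRBV13-3	p30	C25
CGTLDIPMLMQF	TRBV13-3	p30	C25
CGTLDITMLMQF	TRBV13-3	p30	C25
CGTLDITMLMYF	TRBV13-3	p30	C25
CGTLDITMRMQF	TRBV13-3	p30	C25
CGTLDIYMLMQF	TRBV13-3	p30	C25
CGTLDNTMLMQF	TRBV13-3	p30	C25
CGTLDRPMLMQF	TRBV13-3	p30	C25
CGTLLIFMRMQF	TRBV13-3	p30	C25
CGTLLIFMRNQF	TRBV13-3	p30	C25
CGTLPIMMLMYF	TRBV13-3	p30	C25
CGTLQIFMRMQF	TRBV13-3	p30	C25
CGTLQIFMVMQF	TRBV13-3	p30	C25
CGTPLFFMRMQF	TRBV13-3	p30	C25
CGTPLIFMRMQF	TRBV13-3	p30	C25
CSTLDIMMLMQF	TRBV13-3	p30	C25
CSTLEIMMLMQF	TRBV13-3	p30	C25
CAPIPRLTLGYHF	TRBV19	p30	C26
CDPIPRLTLGYHF	TRBV19	p30	C26
CDPIPRLTLVYHF	TRBV19	p30	C26
CPPIPRLTLGYHF	TRBV19	p30	C26
CPPIPRLTLMYEF	TRBV19	p30	C26
CPPIPRLTLMYHF	TRBV19	p30	C26
CPPIPRPTLGYHF	TRBV19	p30	C26
CWPIPELTLFYHF	TRBV19	p30	C26
CWPIPMLTLFYHF	TRBV19	p30	C26
CWPIPMLTLGYHF	TRBV19	p30	C26
CWPIPRDTLGYCF	TRBV19	p30	C26
CWPIPRLTLGYCF	TRBV19	p30	C26
CWPIPRLTLGYDF	TRBV19	p30	C26
CWPIPRLTLGYHF	TRBV19	p30	C26
CWPIPRLTLGYKF	TRBV19	p30	C26
CWPIPRLTMAYHF	TRBV19	p30	C26
CWPIPRLTMAYMF	TRBV19	p30	C26
CWPIPRLTMGYHF	TRBV19	p30	C26
CHCPPCQKLCKTQLF	TRBV4	p30	C30
CHCPPCWKLCKTQKF	TRBV4	p30	C30
CHCPPCWKLCKTQLF	TRBV4	p30	C30
CYCPPCWKLCKTQLF	TRBV4	p30	C30
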