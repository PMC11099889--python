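<?xml version="1.0" encoding="UTF-8"?>
<!-- Subset of the ProXL cross-link results import vocabulary used by this
     package: one search program, one linker declaration, reported cross-link
     peptides with linked positions, and their PSMs. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:element name="proxl_input">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="search_program">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="version" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="linker">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="mass" type="xs:decimal" use="required"/>
            <xs:attribute name="linkable_residues" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="reported_peptides">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="reported_peptide" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="peptide" minOccurs="2" maxOccurs="2">
                      <xs:complexType>
                        <xs:attribute name="sequence" type="xs:string" use="required"/>
                        <xs:attribute name="linked_position" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="protein" type="xs:string" use="required"/>
                        <xs:attribute name="protein_site" type="xs:positiveInteger" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="psms">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="psm" minOccurs="1" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="run" type="xs:string" use="required"/>
                              <xs:attribute name="scan" type="xs:string" use="required"/>
                              <xs:attribute name="charge" type="xs:positiveInteger" use="required"/>
                              <xs:attribute name="precursor_mz" type="xs:decimal" use="required"/>
                              <xs:attribute name="score" type="xs:decimal" use="required"/>
                              <xs:attribute name="q_value" type="xs:decimal" use="optional"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="type" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="fasta_filename" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
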