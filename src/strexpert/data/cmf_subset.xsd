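<?xml version="1.0" encoding="UTF-8"?>
<!-- Documented subset of the CODIS CMF 3.2 exchange format: specimen, locus
     and allele elements only. Full CODIS schema compliance is out of scope. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="CODISImportFile">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="HeaderVersion" type="xs:string" minOccurs="0"/>
        <xs:element name="SpecimenDetail" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="SpecimenID" type="xs:string"/>
              <xs:element name="SpecimenCategory" type="xs:string" minOccurs="0"/>
              <xs:element name="Locus" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="LocusName" type="xs:string"/>
                    <xs:element name="Kit" type="xs:string" minOccurs="0"/>
                    <xs:element name="Allele" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="AlleleValue" type="xs:string"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="ProfileCategory" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="Kit" type="xs:string"/>
      <xs:attribute name="SourceLab" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
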