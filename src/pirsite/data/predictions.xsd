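<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">
  <xs:element name="site-predictions">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="proteins">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="protein" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:choice minOccurs="0" maxOccurs="unbounded">
                    <xs:element name="feature">
                      <xs:complexType>
                        <xs:attribute name="rule" type="xs:string" use="required"/>
                        <xs:attribute name="key" type="xs:string" use="required"/>
                        <xs:attribute name="from" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="to" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="description" type="xs:string"/>
                        <xs:attribute name="evidence" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="keyword">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="rule" type="xs:string" use="required"/>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="comment">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="rule" type="xs:string" use="required"/>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                  </xs:choice>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="nucleotide-id" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="tool" type="xs:string" use="required"/>
      <xs:anyAttribute processContents="skip"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
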